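"""End-to-end workflow: (simulate | load) -> preprocess -> harmonize ->
rhythm detection on the two platforms and their concatenation -> cross-
platform correlation -> PSEA -> candidate annotation -> truth recovery.

All intermediates are written as plain-text tables to the output directory
and a JSON manifest records version, seed and parameters, so a rerun with
the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from circaweld.data import ExpressionMatrix, GeneSetCollection, read_gene_list
from circaweld import simulate as sim
from circaweld.preprocess import filter_expressed, preprocess_counts
from circaweld.harmonize import (
    fit_tdm,
    apply_tdm,
    normalize_to_shared,
    concatenate_series,
)
from circaweld.rhythm import rhythmicity_table, write_fits
from circaweld.corr import compare_platforms, expression_correlation
from circaweld.psea import run_psea, write_psea

log = logging.getLogger("circaweld")

PERIOD_H = 24.0


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Exactly one of ``simulate`` (generator parameters) or ``inputs`` (file
    paths: intensity_tsv, counts_tsv, samples_tsv) must be given.  Cutoffs
    default to the analysis conventions: 0.5 mean CPM and mean intensity 3
    for expressed genes, q < 0.05 with relative amplitude >= 0.1 for
    rhythmicity, and >= 5 rhythmic members per PSEA set.
    """

    out_dir: str = "circaweld_out"
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    shared_window: tuple[float, float] = (12.0, 24.0)
    cpm_cutoff: float = 0.5
    intensity_cutoff: float = 3.0
    q_cut: float = 0.05
    relamp_cut: float = 0.1
    min_genes: int = 5
    gene_sets_gmt: str | None = None
    candidate_lists: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'simulate' and 'inputs' must be configured"
            )
        if not 0 <= self.q_cut <= 1:
            raise ValueError("q_cut must be in [0, 1]")
        if self.relamp_cut < 0:
            raise ValueError("relamp_cut must be >= 0")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        self.shared_window = tuple(float(v) for v in self.shared_window)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shared_window"] = list(self.shared_window)
        return d


def default_simulate_config(seed: int = 0, out_dir: str = "circaweld_out") -> PipelineConfig:
    """The default synthetic study design: 10,000 genes, 20% rhythmic,
    relative amplitudes 0.2-0.6, uniform phases, both platform grids."""
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        simulate={
            "n_genes": 10000,
            "frac_rhythmic": 0.2,
            "phase_mode": "uniform",
            "relamp_range": [0.2, 0.6],
            "gene_sets": {"n_sets": 50, "n_clustered": 10, "set_size": 20, "window_h": 1.0},
        },
    )


def _stage(name):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return False

    return _Ctx()


def analyze_two_platforms(
    intensity: ExpressionMatrix,
    counts: ExpressionMatrix,
    shared_window: tuple[float, float] = (12.0, 24.0),
    cpm_cutoff: float = 0.5,
    intensity_cutoff: float = 3.0,
    q_cut: float = 0.05,
    relamp_cut: float = 0.1,
) -> dict:
    """Core two-platform analysis without file I/O.

    Filters each platform (mean intensity / mean CPM with TMM
    renormalization), restricts to the commonly expressed genes, TDM-matches
    the count platform to the intensity platform, normalizes both to the
    shared window, concatenates, and fits the cosinor model to the two
    single platforms (on original linear values) and the concatenation.

    Returns a dict with ``fits`` (three rhythmicity tables), ``tdm``,
    ``concatenated``, and the filtered per-platform matrices.
    """
    intensity_f = filter_expressed(intensity, intensity_cutoff)
    logcpm, lincpm, factors = preprocess_counts(counts, cpm_cutoff)
    common = intensity_f.gene_ids.intersection(logcpm.gene_ids)
    intensity_f = intensity_f.subset_genes(common)
    logcpm = logcpm.subset_genes(common)
    lincpm = lincpm.subset_genes(common)

    tdm = fit_tdm(intensity_f, logcpm)
    matched = apply_tdm(logcpm, tdm)
    concat = concatenate_series(
        normalize_to_shared(intensity_f, shared_window),
        normalize_to_shared(matched, shared_window),
        shared_window,
    )
    fits = {
        "microarray": rhythmicity_table(
            intensity_f.to_linear(), PERIOD_H, q_cut, relamp_cut
        ),
        "rnaseq": rhythmicity_table(lincpm, PERIOD_H, q_cut, relamp_cut),
        "concatenated": rhythmicity_table(concat, PERIOD_H, q_cut, relamp_cut),
    }
    return {
        "fits": fits,
        "tdm": tdm,
        "concatenated": concat,
        "intensity_expressed": intensity_f,
        "logcpm": logcpm,
        "lincpm": lincpm,
        "factors": factors,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write all outputs to config.out_dir.

    Returns a result bundle with the three rhythmicity tables, the
    correlation report, the PSEA table, the candidate table, the recovery
    metrics (simulate mode), and the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_of: dict[str, int] = {}

    truth = None
    gene_sets = None
    with _stage("simulate/load"):
        if config.simulate is not None:
            p = dict(config.simulate)
            gs_cfg = p.pop("gene_sets", None)
            phase_mode = p.pop("phase_mode", "uniform")
            if isinstance(phase_mode, list):
                phase_mode = tuple(phase_mode)
            relamp_range = tuple(p.pop("relamp_range", (0.2, 0.6)))
            noise_sd = p.pop("noise_sd", sim.DEFAULT_INTENSITY_NOISE_SD)
            dispersion = p.pop("dispersion", sim.DEFAULT_NB_DISPERSION)
            truth = sim.simulate_truth(
                p.pop("n_genes", 10000),
                p.pop("frac_rhythmic", 0.2),
                phase_mode,
                relamp_range,
                seed=config.seed,
                **p,
            )
            intensity = sim.render_intensity(
                truth, sim.intensity_profile(noise_sd=noise_sd), seed=config.seed + 1
            )
            counts = sim.render_counts(
                truth, sim.counts_profile(dispersion=dispersion), seed=config.seed + 2
            )
            sim.write_truth(truth, out / "truth.tsv")
            if gs_cfg is not None:
                gene_sets = sim.simulate_gene_sets(
                    truth, seed=config.seed + 3, **gs_cfg
                )
                gene_sets.to_gmt(out / "gene_sets.gmt")
        else:
            paths = config.inputs
            intensity = ExpressionMatrix.from_tsv(
                paths["intensity_tsv"], paths["samples_tsv"], "log2-intensity"
            )
            counts = ExpressionMatrix.from_tsv(
                paths["counts_tsv"], paths["samples_tsv"], "counts"
            )
            intensity = ExpressionMatrix(
                intensity.values.loc[:, intensity.platform == "microarray"],
                intensity.sample_time_h,
                intensity.platform,
                "log2-intensity",
            )
            counts = ExpressionMatrix(
                counts.values.loc[:, counts.platform == "rnaseq"],
                counts.sample_time_h,
                counts.platform,
                "counts",
            )
        if config.gene_sets_gmt is not None:
            gene_sets = GeneSetCollection.from_gmt(config.gene_sets_gmt)
    counts_of["genes_intensity_raw"] = intensity.n_genes
    counts_of["genes_counts_raw"] = counts.n_genes

    with _stage("preprocess/harmonize/rhythm"):
        analysis = analyze_two_platforms(
            intensity,
            counts,
            shared_window=config.shared_window,
            cpm_cutoff=config.cpm_cutoff,
            intensity_cutoff=config.intensity_cutoff,
            q_cut=config.q_cut,
            relamp_cut=config.relamp_cut,
        )
        intensity_f = analysis["intensity_expressed"]
        logcpm = analysis["logcpm"]
        concat = analysis["concatenated"]
        fits = analysis["fits"]
        with open(out / "tdm_params.json", "w") as fh:
            json.dump(analysis["tdm"].to_dict(), fh, indent=2, sort_keys=True)
        concat.matrix.to_tsv(out / "concatenated.tsv", out / "concatenated_samples.tsv")
        for name, table in fits.items():
            write_fits(table, out / f"rhythm_{name}.tsv")
    counts_of["genes_intensity_expressed"] = intensity_f.n_genes
    counts_of["genes_counts_expressed"] = logcpm.n_genes
    counts_of["genes_common_expressed"] = intensity_f.n_genes
    counts_of["samples_concatenated"] = concat.matrix.n_samples
    log.info(
        "expressed genes: intensity %d, counts %d (common universe)",
        counts_of["genes_intensity_expressed"],
        counts_of["genes_counts_expressed"],
    )
    for name, table in fits.items():
        counts_of[f"rhythmic_{name}"] = int(table["significant"].sum())
        log.info("24-h rhythmic genes (%s): %d", name, counts_of[f"rhythmic_{name}"])

    with _stage("corr"):
        report = compare_platforms(fits["microarray"], fits["rnaseq"])
        report.mean_pearson = expression_correlation(
            intensity_f, logcpm, shared_times=None
        )
        with open(out / "correlation.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)

    psea_table = None
    if gene_sets is not None:
        with _stage("psea"):
            psea_table = run_psea(
                fits["concatenated"], gene_sets, config.min_genes, config.q_cut
            )
            write_psea(psea_table, out / "psea.tsv")
            counts_of["psea_enriched"] = int(psea_table["enriched"].sum())

    with _stage("annotate"):
        lists = {
            name: read_gene_list(path)
            for name, path in sorted(config.candidate_lists.items())
        }
        candidates, cand_summary = annotate_candidates(fits, lists)
        candidates.to_csv(out / "candidates.tsv", sep="\t")

    recovery = None
    if truth is not None:
        with _stage("recovery"):
            recovery = recovery_report(truth, fits["concatenated"])
            with open(out / "recovery.json", "w") as fh:
                json.dump(recovery, fh, indent=2, sort_keys=True)

    manifest = {
        "package": "circaweld",
        "version": __import__("circaweld").__version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "gene_counts": counts_of,
        "candidate_summary": cand_summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "truth": truth,
        "fits": fits,
        "correlation": report,
        "psea": psea_table,
        "candidates": candidates,
        "candidate_summary": cand_summary,
        "recovery": recovery,
        "concatenated": concat,
        "manifest": manifest,
    }


def annotate_candidates(
    fits_per_dataset: dict[str, pd.DataFrame], lists: dict[str, list[str]]
):
    """Merge candidate gene lists against the significant genes of each dataset.

    A gene enters the table when it is significant in at least one dataset
    and occurs in at least one list; its row records every matching list and
    the per-dataset significance flags and phases.  The summary reports the
    per-list matched totals and the unique union count (e.g. lists of sizes
    55 and 39 overlapping in 2 genes yield 92 unique candidates).
    """
    significant_any: set[str] = set()
    for table in fits_per_dataset.values():
        significant_any |= set(table.index[table["significant"]])
    rows = []
    per_list: dict[str, int] = {}
    for lname, genes in lists.items():
        genes = list(dict.fromkeys(genes))
        matched = [g for g in genes if g in significant_any]
        per_list[lname] = len(matched)
        if not matched:
            log.warning("candidate list %r has no rhythmic overlap", lname)
    all_listed = sorted(
        {g for genes in lists.values() for g in genes if g in significant_any}
    )
    for g in all_listed:
        row: dict = {
            "gene_id": g,
            "lists": ",".join(sorted(n for n, genes in lists.items() if g in genes)),
        }
        for dname, table in fits_per_dataset.items():
            if g in table.index:
                row[f"significant_{dname}"] = bool(table.at[g, "significant"])
                row[f"phase_{dname}"] = float(table.at[g, "phase_h"])
            else:
                row[f"significant_{dname}"] = False
                row[f"phase_{dname}"] = float("nan")
        rows.append(row)
    columns = ["gene_id", "lists"] + [
        f"{k}_{d}" for d in fits_per_dataset for k in ("significant", "phase")
    ]
    table = pd.DataFrame(rows, columns=columns).set_index("gene_id")
    summary = {"per_list": per_list, "unique_total": len(all_listed)}
    log.info("candidate summary: %s", summary)
    return table, summary


def recovery_report(truth: pd.DataFrame, fits: pd.DataFrame) -> dict:
    """Score a rhythmicity table against the simulated ground truth.

    The fitted gene universe may be a subset of the truth's (genes removed
    by expression filters count as misses); genes unknown to the truth are
    rejected.  Phase errors are circular: min(|d|, 24 - |d|).
    """
    unknown = fits.index.difference(truth.index)
    if len(unknown):
        raise ValueError(f"fits contain genes unknown to the truth: {list(unknown[:5])}")
    rhythmic = set(truth.index[truth["is_rhythmic"]])
    significant = set(fits.index[fits["significant"]])
    tp = significant & rhythmic
    fp = significant - rhythmic
    sensitivity = len(tp) / len(rhythmic) if rhythmic else None
    fdr = len(fp) / len(significant) if significant else 0.0
    if tp:
        tp_idx = sorted(tp)
        d = np.abs(
            fits.loc[tp_idx, "phase_h"].to_numpy()
            - truth.loc[tp_idx, "phase_true"].to_numpy()
        )
        phase_err = np.minimum(d, PERIOD_H - d)
        median_phase_error_h = float(np.median(phase_err))
        ra_true = truth.loc[tp_idx, "relamp_true"].to_numpy()
        ra_est = fits.loc[tp_idx, "relamp"].to_numpy()
        median_relamp_rel_error = float(
            np.median(np.abs(ra_est - ra_true) / ra_true)
        )
    else:
        median_phase_error_h = None
        median_relamp_rel_error = None
    return {
        "n_true_rhythmic": len(rhythmic),
        "n_significant": len(significant),
        "n_true_positive": len(tp),
        "sensitivity": sensitivity,
        "fdr": fdr,
        "median_phase_error_h": median_phase_error_h,
        "median_relamp_rel_error": median_relamp_rel_error,
    }
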