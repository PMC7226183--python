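"""Two-platform synthetic circadian time-series generator with known truth.

Emulates the study design the pipeline targets: a bounded log2-intensity
platform sampled 0-24 h every 3 h (9 samples, 24 h replicating 0 h
circadianly) and a count platform with a wider dynamic range sampled
12-42 h every 3 h (11 samples, 36/39/42 h replicating 12/15/18 h).

Every rhythmic gene follows a pure single-harmonic cosine

    s_g(t) = mesor_g * (1 + relamp_g * cos(2*pi*(t - phase_g)/24))

rendered with additive Gaussian noise on the log2-intensity platform and
negative-binomial sampling on the count platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from circaweld.data import ExpressionMatrix

PERIOD_H = 24.0

#: Defaults of the synthetic design (see docs/methods.md for rationale).
DEFAULT_BASELINE_MEAN_LOG2 = 7.0
DEFAULT_BASELINE_SD_LOG2 = 2.0
DEFAULT_INTENSITY_NOISE_SD = 0.15  # log2 units
DEFAULT_NB_DISPERSION = 0.05
DEFAULT_LIBRARY_SIZE = 5e6


@dataclass
class PlatformProfile:
    """Rendering profile of one measurement platform.

    ``noise_scale`` is the Gaussian sd in log2 units for the intensity kind
    and the negative-binomial dispersion (var = mu + disp*mu^2) for the
    counts kind.  ``replicate_times`` maps each wall time to its circadian
    equivalent (t mod 24); replicate wall times receive independent noise.
    """

    kind: str  # "intensity" | "counts"
    time_grid: np.ndarray
    noise_scale: float
    intensity_range: tuple[float, float] | None = None
    library_sizes: np.ndarray | None = None
    replicate_times: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("intensity", "counts"):
            raise ValueError(f"unknown platform kind {self.kind!r}")
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.time_grid.ndim != 1 or len(self.time_grid) < 1:
            raise ValueError("time_grid must be a non-empty 1-D sequence")
        if not np.all(np.diff(self.time_grid) > 0):
            raise ValueError("time_grid must be strictly increasing")
        if self.kind == "intensity" and self.intensity_range is None:
            self.intensity_range = (0.0, 13.5)
        if self.kind == "counts":
            if self.library_sizes is None:
                raise ValueError("counts profile needs library_sizes")
            self.library_sizes = np.asarray(self.library_sizes, dtype=float)
            if len(self.library_sizes) != len(self.time_grid):
                raise ValueError("library_sizes must match time_grid length")
            if np.any(self.library_sizes <= 0):
                raise ValueError("library sizes must be positive")
        if not self.replicate_times:
            self.replicate_times = {
                float(t): float(t % PERIOD_H) for t in self.time_grid
            }


def intensity_profile(
    time_grid=None,
    noise_sd: float = DEFAULT_INTENSITY_NOISE_SD,
    intensity_range: tuple[float, float] = (0.0, 13.5),
) -> PlatformProfile:
    """Microarray-like design: 0-24 h every 3 h, bounded log2 intensities."""
    if time_grid is None:
        time_grid = np.arange(0.0, 24.1, 3.0)  # 9 samples; 24 h replicates 0 h
    return PlatformProfile(
        kind="intensity",
        time_grid=time_grid,
        noise_scale=noise_sd,
        intensity_range=intensity_range,
    )


def counts_profile(
    time_grid=None,
    dispersion: float = DEFAULT_NB_DISPERSION,
    library_sizes=None,
) -> PlatformProfile:
    """RNA-seq-like design: 12-42 h every 3 h, NB counts.

    Default library sizes ramp deterministically over +-10% of 5e6 so that
    between-sample normalization has real work to do.
    """
    if time_grid is None:
        time_grid = np.arange(12.0, 42.1, 3.0)  # 11 samples; 36/39/42 h replicate
    time_grid = np.asarray(time_grid, dtype=float)
    if library_sizes is None:
        n = len(time_grid)
        ramp = np.linspace(0.9, 1.1, n) if n > 1 else np.array([1.0])
        library_sizes = DEFAULT_LIBRARY_SIZE * ramp
    return PlatformProfile(
        kind="counts",
        time_grid=time_grid,
        noise_scale=dispersion,
        library_sizes=library_sizes,
    )


def simulate_truth(
    n_genes: int,
    frac_rhythmic: float = 0.2,
    phase_mode="uniform",
    relamp_range: tuple[float, float] = (0.2, 0.6),
    seed: int = 0,
    baseline_mean_log2: float = DEFAULT_BASELINE_MEAN_LOG2,
    baseline_sd_log2: float = DEFAULT_BASELINE_SD_LOG2,
) -> pd.DataFrame:
    """Draw ground-truth rhythm parameters for ``n_genes`` genes.

    Parameters
    ----------
    frac_rhythmic
        Fraction of genes carrying a 24-h cosine; exactly
        ``round(n_genes * frac_rhythmic)`` genes are flagged rhythmic.
    phase_mode
        ``"uniform"`` for phases uniform on [0, 24), or
        ``("clustered", center_h, sd_h)`` for wrapped-normal phases.
    relamp_range
        ``(lo, hi)`` bounds of the uniform relative-amplitude draw,
        0 < lo <= hi <= 1.

    Returns
    -------
    DataFrame indexed by gene_id with columns is_rhythmic, mesor_true,
    relamp_true, phase_true (NaN for arrhythmic genes),
    baseline_log_abundance.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= frac_rhythmic <= 1.0:
        raise ValueError(f"frac_rhythmic must be in [0, 1], got {frac_rhythmic}")
    lo, hi = relamp_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError(f"relamp_range must satisfy 0 < lo <= hi <= 1, got {relamp_range}")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]

    n_rhythmic = int(round(n_genes * frac_rhythmic))
    is_rhythmic = np.zeros(n_genes, dtype=bool)
    is_rhythmic[rng.choice(n_genes, size=n_rhythmic, replace=False)] = True

    baseline = rng.normal(baseline_mean_log2, baseline_sd_log2, size=n_genes)
    mesor = np.exp2(baseline)

    relamp = np.zeros(n_genes)
    relamp[is_rhythmic] = rng.uniform(lo, hi, size=n_rhythmic)

    phase = np.full(n_genes, np.nan)
    if n_rhythmic:
        if phase_mode == "uniform":
            drawn = rng.uniform(0.0, PERIOD_H, size=n_rhythmic)
        elif isinstance(phase_mode, (tuple, list)) and phase_mode[0] == "clustered":
            _, center_h, sd_h = phase_mode
            drawn = np.mod(rng.normal(center_h, sd_h, size=n_rhythmic), PERIOD_H)
        else:
            raise ValueError(f"unknown phase_mode {phase_mode!r}")
        phase[is_rhythmic] = drawn

    return pd.DataFrame(
        {
            "is_rhythmic": is_rhythmic,
            "mesor_true": mesor,
            "relamp_true": relamp,
            "phase_true": phase,
            "baseline_log_abundance": baseline,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def _noiseless_signal(truth: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    """Linear-scale signal matrix (genes x times) of the cosine model."""
    mesor = truth["mesor_true"].to_numpy()[:, None]
    relamp = truth["relamp_true"].to_numpy()[:, None]
    phase = np.nan_to_num(truth["phase_true"].to_numpy())[:, None]
    omega = 2.0 * np.pi / PERIOD_H
    return mesor * (1.0 + relamp * np.cos(omega * (times[None, :] - phase)))


def render_intensity(
    truth: pd.DataFrame, profile: PlatformProfile | None = None, seed: int = 0
) -> ExpressionMatrix:
    """Render the truth on the bounded log2-intensity platform.

    Emitted value = clamp(log2 s_g(t) + N(0, noise_scale), intensity_range).
    """
    if profile is None:
        profile = intensity_profile()
    if profile.kind != "intensity":
        raise ValueError("render_intensity needs an intensity-kind profile")
    rng = np.random.default_rng(seed)
    times = profile.time_grid
    signal = _noiseless_signal(truth, times)
    values = np.log2(signal)
    if profile.noise_scale > 0:
        values = values + rng.normal(0.0, profile.noise_scale, size=values.shape)
    lo, hi = profile.intensity_range
    values = np.clip(values, lo, hi)
    sample_ids = [f"MA_{t:04.1f}h" for t in times]
    df = pd.DataFrame(values, index=truth.index, columns=sample_ids)
    return ExpressionMatrix(
        df,
        pd.Series(times, index=sample_ids),
        "microarray",
        "log2-intensity",
    )


def render_counts(
    truth: pd.DataFrame, profile: PlatformProfile | None = None, seed: int = 0
) -> ExpressionMatrix:
    """Render the truth on the count platform.

    The noiseless signal is interpreted on a CPM-like scale, so the NB mean
    is mu_gs = s_g(t) * library_size_s / 1e6 with variance mu + disp*mu^2.
    """
    if profile is None:
        profile = counts_profile()
    if profile.kind != "counts":
        raise ValueError("render_counts needs a counts-kind profile")
    rng = np.random.default_rng(seed)
    times = profile.time_grid
    libs = profile.library_sizes
    mu = _noiseless_signal(truth, times) * (libs[None, :] / 1e6)
    disp = profile.noise_scale
    if disp <= 0:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / disp
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    sample_ids = [f"RS_{t:04.1f}h" for t in times]
    df = pd.DataFrame(counts.astype(np.int64), index=truth.index, columns=sample_ids)
    return ExpressionMatrix(
        df,
        pd.Series(times, index=sample_ids),
        "rnaseq",
        "counts",
    )


def simulate_gene_sets(
    truth: pd.DataFrame,
    n_sets: int = 50,
    n_clustered: int = 10,
    set_size: int = 20,
    window_h: float = 1.0,
    seed: int = 0,
):
    """Generate labelled gene sets for phase-enrichment benchmarking.

    ``n_clustered`` sets draw members from rhythmic genes whose true phase
    lies within a window of width ``window_h`` around a random center; the
    remaining sets draw members from all genes irrespective of phase.  The
    ground-truth label of each set ("clustered"/"null") is recorded.
    """
    from circaweld.data import GeneSetCollection

    if n_clustered > n_sets:
        raise ValueError("n_clustered must be <= n_sets")
    if set_size < 5:
        raise ValueError("set_size must be >= 5 to survive the PSEA size filter")
    rng = np.random.default_rng(seed)
    phases = truth.loc[truth["is_rhythmic"], "phase_true"]
    sets: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    width = len(str(n_sets))
    for i in range(n_sets):
        name = f"SET{i + 1:0{width}d}"
        if i < n_clustered:
            center = rng.uniform(0.0, PERIOD_H)
            delta = np.abs(phases.to_numpy() - center)
            circ = np.minimum(delta, PERIOD_H - delta)
            pool = phases.index[circ <= window_h / 2.0]
            if len(pool) < set_size:
                raise ValueError(
                    f"only {len(pool)} rhythmic genes in the {window_h} h window "
                    f"around {center:.2f} h; need {set_size}"
                )
            members = list(rng.choice(pool, size=set_size, replace=False))
            labels[name] = "clustered"
            descriptions[name] = f"clustered|center={center:.2f}|window={window_h}"
        else:
            members = list(rng.choice(truth.index, size=set_size, replace=False))
            labels[name] = "null"
            descriptions[name] = "null"
        sets[name] = sorted(members)
    return GeneSetCollection(sets, descriptions, labels)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", index_col="gene_id")
    truth["is_rhythmic"] = truth["is_rhythmic"].astype(bool)
    return truth
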