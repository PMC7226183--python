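"""Platform-level preprocessing: feature-to-gene collapse, TMM/CPM count
normalization and mean-expression filtering.

TMM (trimmed mean of M-values) follows the published definition: M- and
A-values of each sample against a reference sample (the one whose upper
quartile of count/library-size is closest to the mean upper quartile), a 30%
two-sided trim on M and 5% on A, and an inverse-asymptotic-variance weighted
mean of the retained M-values as the log2 scaling factor.  Factors are
centred to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from circaweld.data import ExpressionMatrix


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors and effective library sizes."""

    factor_per_sample: pd.Series
    library_size: pd.Series
    reference_sample: str

    def __post_init__(self) -> None:
        log_f = np.log(self.factor_per_sample.to_numpy())
        if abs(log_f.mean()) > 1e-9:
            raise ValueError("factors must have geometric mean 1")

    @property
    def effective_library_size(self) -> pd.Series:
        return self.library_size * self.factor_per_sample


def collapse_features(matrix: ExpressionMatrix, feature_to_gene) -> ExpressionMatrix:
    """Collapse a feature-level matrix to gene level.

    For genes annotated by multiple features, the feature with the highest
    mean expression over all time points represents the gene; ties go to the
    lexicographically smallest feature id.  Unmapped features are dropped.
    """
    mapping = pd.Series(dict(feature_to_gene))
    if mapping.empty:
        raise ValueError("feature_to_gene mapping is empty")
    mapping = mapping[mapping.index.isin(matrix.gene_ids)]
    if mapping.empty:
        raise ValueError("no mapped feature is present in the matrix")

    means = matrix.values.mean(axis=1)
    chosen: dict[str, str] = {}
    for gene, features in mapping.groupby(mapping).groups.items():
        feats = sorted(features)  # lexicographic tie-break
        # max() keeps the first of equal keys, i.e. the smallest feature id
        chosen[gene] = max(feats, key=lambda f: means[f])
    genes = sorted(chosen)
    values = matrix.values.loc[[chosen[g] for g in genes]]
    values.index = pd.Index(genes, name="gene_id")
    return matrix.with_values(values, matrix.scale)


def read_feature_map(path) -> dict[str, str]:
    """Read a two-column TSV (feature_id, gene_id) into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "gene_id"])
    return dict(zip(df["feature_id"], df["gene_id"]))


def _quantile_factor(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.array(
        [np.quantile(counts[:, j], p) / lib[j] for j in range(counts.shape[1])]
    )


def tmm_factors(
    counts: ExpressionMatrix,
    reference_sample: str | None = None,
    log_ratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors for a count matrix."""
    if counts.scale != "counts":
        raise ValueError("tmm_factors expects a counts-scale matrix")
    if counts.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = counts.values.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    zero = lib == 0
    if zero.any():
        bad = list(counts.sample_ids[zero])
        raise ValueError(f"all-zero sample(s): {bad}")
    if not np.any((x > 0).all(axis=1)):
        raise ValueError("need at least one gene with positive counts in every sample")

    samples = list(counts.sample_ids)
    if reference_sample is None:
        f75 = _quantile_factor(x, lib)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = samples.index(reference_sample)

    ref = x[:, ref_idx] / lib[ref_idx]
    log_factors = np.zeros(len(samples))
    for j in range(len(samples)):
        if j == ref_idx:
            continue
        obs = x[:, j] / lib[j]
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep], ref[keep]
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        # asymptotic variance of M (delta method on binomial counts)
        v = (lib[j] - x[keep, j]) / (lib[j] * x[keep, j]) + (
            lib[ref_idx] - x[keep, ref_idx]
        ) / (lib[ref_idx] * x[keep, ref_idx])
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = len(m)
        lo_l = np.floor(n * log_ratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * abs_expr_trim) + 1
        hi_s = n + 1 - lo_s
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        sel = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
        if not sel.any():
            continue
        log_factors[j] = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])

    factors = 2.0 ** (log_factors - log_factors.mean())  # geometric mean 1
    return NormFactors(
        factor_per_sample=pd.Series(factors, index=counts.sample_ids),
        library_size=pd.Series(lib, index=counts.sample_ids),
        reference_sample=samples[ref_idx],
    )


def cpm(
    counts: ExpressionMatrix,
    factors: NormFactors | None = None,
    prior_count: float = 0.0,
    log: bool = False,
) -> ExpressionMatrix:
    """Counts per million with optional TMM factors and log2 transform.

    With ``log=True`` the prior count is scaled by relative library size (the
    standard CPM convention): value = log2((count + prior_s) /
    (effective_lib_s + 2 * prior_s) * 1e6) with prior_s = prior_count *
    lib_s / mean(lib).
    """
    if counts.scale != "counts":
        raise ValueError("cpm expects a counts-scale matrix")
    if prior_count < 0:
        raise ValueError("prior_count must be >= 0")
    x = counts.values.to_numpy(dtype=float)
    if factors is None:
        lib = x.sum(axis=0)
    else:
        lib = factors.effective_library_size.reindex(counts.sample_ids).to_numpy()
    if log:
        prior = prior_count * lib / lib.mean()
        vals = np.log2((x + prior[None, :]) / (lib + 2 * prior)[None, :] * 1e6)
        scale = "log2-cpm"
    else:
        vals = (x + prior_count) / lib[None, :] * 1e6
        scale = "linear"
    df = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)
    return counts.with_values(df, scale)


def log_cpm(
    counts: ExpressionMatrix,
    factors: NormFactors | None = None,
    prior_count: float = 0.5,
) -> ExpressionMatrix:
    """log2 counts per million (see :func:`cpm` with ``log=True``)."""
    return cpm(counts, factors, prior_count=prior_count, log=True)


def filter_expressed(
    matrix: ExpressionMatrix,
    cutoff: float,
    factors: NormFactors | None = None,
) -> ExpressionMatrix:
    """Keep genes whose mean expression over all samples is >= cutoff.

    For a counts matrix the mean is evaluated on the CPM scale (TMM factors
    computed on the fly when not supplied) and the *counts* of the retained
    genes are returned, ready for renormalization (recompute TMM, then CPM,
    on the retained gene set).  For any other scale the mean of the stored
    values is compared with the cutoff directly.
    """
    if np.isnan(cutoff) or cutoff == np.inf:
        raise ValueError("cutoff must be finite or -inf")
    if matrix.scale == "counts":
        if factors is None:
            factors = tmm_factors(matrix)
        means = cpm(matrix, factors).values.mean(axis=1)
    else:
        means = matrix.values.mean(axis=1)
    keep = means >= cutoff
    if not keep.any():
        raise ValueError(
            f"cutoff {cutoff} removes all {matrix.n_genes} genes"
        )
    return matrix.with_values(matrix.values.loc[keep], matrix.scale)


def preprocess_counts(
    counts: ExpressionMatrix,
    cutoff: float = 0.5,
    prior_count: float = 0.5,
) -> tuple[ExpressionMatrix, ExpressionMatrix, NormFactors]:
    """Filter counts at a mean-CPM cutoff, renormalize, and transform.

    Returns (log2-CPM matrix, linear CPM matrix, TMM factors), all computed
    on the retained gene set only.
    """
    filtered = filter_expressed(counts, cutoff)
    factors = tmm_factors(filtered)
    return (
        log_cpm(filtered, factors, prior_count=prior_count),
        cpm(filtered, factors),
        factors,
    )
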