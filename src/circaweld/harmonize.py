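"""Cross-platform harmonization: Training Distribution Matching, shared-window
normalization, and concatenation into one long time series.

TDM maps the pooled value distribution of a target dataset (log2 CPM from the
count platform) onto the range of a reference dataset (log2 intensities): the
reference's quartile-relative spreads below Q1 and above Q3 define clamp
bounds on the target's own quartiles; target values are clamped into those
bounds and linearly rescaled onto [ref_min, ref_max].  The map is global and
monotone, so within-sample and within-gene rank order is preserved.

After TDM each platform is normalized per gene, on the linear scale, to its
mean over the shared time window (default 12-24 h inclusive), which removes
gene-specific platform offsets; the two normalized series are then pooled
over the union time grid with equal-time samples treated as replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from circaweld.data import ExpressionMatrix

SHARED_WINDOW_DEFAULT = (12.0, 24.0)


@dataclass
class TDMParams:
    """Fitted parameters of the Training Distribution Matching transform."""

    ref_min: float
    ref_max: float
    ref_q1: float
    ref_q3: float
    target_q1: float
    target_q3: float

    @property
    def ref_iqr(self) -> float:
        return self.ref_q3 - self.ref_q1

    @property
    def target_iqr(self) -> float:
        return self.target_q3 - self.target_q1

    @property
    def spread_low(self) -> float:
        return (self.ref_q1 - self.ref_min) / self.ref_iqr

    @property
    def spread_high(self) -> float:
        return (self.ref_max - self.ref_q3) / self.ref_iqr

    @property
    def clamp_low(self) -> float:
        return self.target_q1 - self.spread_low * self.target_iqr

    @property
    def clamp_high(self) -> float:
        return self.target_q3 + self.spread_high * self.target_iqr

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            spread_low=self.spread_low,
            spread_high=self.spread_high,
            clamp_low=self.clamp_low,
            clamp_high=self.clamp_high,
        )
        return d


@dataclass
class ConcatenatedSeries:
    """One long series pooled from two platforms over the union time grid."""

    matrix: ExpressionMatrix
    shared_window: tuple[float, float]

    @property
    def replicate_groups(self) -> dict[float, list[str]]:
        groups: dict[float, list[str]] = {}
        for sid, t in self.matrix.sample_time_h.items():
            groups.setdefault(float(t), []).append(sid)
        return groups


def fit_tdm(reference: ExpressionMatrix, target: ExpressionMatrix) -> TDMParams:
    """Fit TDM parameters from pooled values of reference and target.

    Both matrices should already be restricted to the commonly expressed
    genes; quartiles and extremes are taken over all pooled values.
    """
    ref = reference.values.to_numpy().ravel()
    tgt = target.values.to_numpy().ravel()
    ref_q1, ref_q3 = np.quantile(ref, [0.25, 0.75])
    tgt_q1, tgt_q3 = np.quantile(tgt, [0.25, 0.75])
    if ref_q3 - ref_q1 <= 0:
        raise ValueError("reference distribution is degenerate (zero IQR)")
    if tgt_q3 - tgt_q1 <= 0:
        raise ValueError("target distribution is degenerate (zero IQR)")
    return TDMParams(
        ref_min=float(ref.min()),
        ref_max=float(ref.max()),
        ref_q1=float(ref_q1),
        ref_q3=float(ref_q3),
        target_q1=float(tgt_q1),
        target_q3=float(tgt_q3),
    )


def apply_tdm(target: ExpressionMatrix, params: TDMParams) -> ExpressionMatrix:
    """Clamp target values into the TDM bounds and rescale onto the reference range."""
    lo, hi = params.clamp_low, params.clamp_high
    if not lo < hi:
        raise ValueError("degenerate clamp bounds")
    x = np.clip(target.values.to_numpy(), lo, hi)
    x = (x - lo) / (hi - lo) * (params.ref_max - params.ref_min) + params.ref_min
    df = pd.DataFrame(x, index=target.gene_ids, columns=target.sample_ids)
    return target.with_values(df, "log2-intensity-matched")


def normalize_to_shared(
    matrix: ExpressionMatrix,
    shared_window: tuple[float, float] = SHARED_WINDOW_DEFAULT,
) -> ExpressionMatrix:
    """Divide each gene, on the linear scale, by its mean over the shared window.

    Log2-scaled inputs are first de-logged (2**x).  Window boundaries are
    inclusive.  After this the per-gene mean over the window samples is
    exactly 1, so independently normalized platforms carry no platform
    offset inside the window.
    """
    lo, hi = shared_window
    linear = matrix.to_linear()
    in_window = (matrix.sample_time_h >= lo) & (matrix.sample_time_h <= hi)
    if not in_window.any():
        raise ValueError(f"no sample inside shared window [{lo}, {hi}] h")
    means = linear.values.loc[:, in_window.to_numpy()].mean(axis=1)
    bad = means.index[means <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive shared-window mean for gene(s): {list(bad[:10])}"
        )
    df = linear.values.div(means, axis=0)
    return matrix.with_values(df, "linear-normalized")


def concatenate_series(
    ref_norm: ExpressionMatrix,
    target_norm: ExpressionMatrix,
    shared_window: tuple[float, float] = SHARED_WINDOW_DEFAULT,
) -> ConcatenatedSeries:
    """Pool two shared-window-normalized platforms into one long series.

    Genes are restricted to the intersection of the two universes; samples
    at equal wall times become replicate groups; the platform of origin is
    retained per sample.
    """
    common = ref_norm.gene_ids.intersection(target_norm.gene_ids)
    if len(common) == 0:
        raise ValueError("gene universes are disjoint")
    common = ref_norm.gene_ids[ref_norm.gene_ids.isin(common)]
    values = pd.concat(
        [ref_norm.values.loc[common], target_norm.values.loc[common]], axis=1
    )
    if not values.columns.is_unique:
        raise ValueError("sample ids collide between the two platforms")
    times = pd.concat([ref_norm.sample_time_h, target_norm.sample_time_h])
    platforms = pd.concat([ref_norm.platform, target_norm.platform])
    order = np.argsort(times.to_numpy(), kind="stable")
    values = values.iloc[:, order]
    matrix = ExpressionMatrix(
        values, times.iloc[order], platforms.iloc[order], "linear-normalized"
    )
    return ConcatenatedSeries(matrix, shared_window)
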