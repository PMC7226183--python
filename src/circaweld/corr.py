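"""Cross-platform comparison statistics.

Three comparisons between platforms: (i) mean per-time-point Pearson
correlation of expression across common genes at shared sampling times,
(ii) circular (Jammalamadaka-SenGupta) correlation of peak phases of
commonly rhythmic genes, and (iii) ordinary Pearson correlation of their
relative amplitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from circaweld.data import ExpressionMatrix

PERIOD_H = 24.0


@dataclass
class CorrelationReport:
    """Cross-platform agreement summary on the common rhythmic gene set."""

    mean_pearson: float
    circular_r: float
    circular_p: float
    amp_r: float
    amp_p: float
    n_genes: int

    def to_dict(self) -> dict:
        return asdict(self)


def expression_correlation(
    A: ExpressionMatrix, B: ExpressionMatrix, shared_times=None
) -> float:
    """Mean over shared time points of the per-time Pearson r across genes.

    At each shared time every replicate sample of A is paired with every
    replicate sample of B and the pairwise coefficients are averaged.
    Zero-variance samples make a time point undefined; such times are
    skipped with a warning.
    """
    common = A.gene_ids.intersection(B.gene_ids)
    if len(common) < 3:
        raise ValueError("need at least 3 common genes")
    if shared_times is None:
        shared_times = sorted(
            set(A.sample_time_h.round(9)) & set(B.sample_time_h.round(9))
        )
    shared_times = list(shared_times)
    if not shared_times:
        raise ValueError("no shared time points")
    coeffs = []
    for t in shared_times:
        cols_a = A.sample_ids[np.isclose(A.sample_time_h, t)]
        cols_b = B.sample_ids[np.isclose(B.sample_time_h, t)]
        if len(cols_a) == 0 or len(cols_b) == 0:
            raise ValueError(f"time {t} h missing from one platform")
        rs = []
        for ca in cols_a:
            for cb in cols_b:
                x = A.values.loc[common, ca].to_numpy()
                y = B.values.loc[common, cb].to_numpy()
                if np.std(x) == 0 or np.std(y) == 0:
                    continue
                rs.append(stats.pearsonr(x, y).statistic)
        if rs:
            coeffs.append(np.mean(rs))
        else:
            warnings.warn(f"zero-variance sample at t={t} h; time point skipped")
    if not coeffs:
        raise ValueError("every shared time point was skipped")
    return float(np.mean(coeffs))


def circular_correlation(phases_x, phases_y, period: float = PERIOD_H):
    """Jammalamadaka-SenGupta circular correlation of two phase vectors.

    Phases in hours are converted to angles theta = 2*pi*phase/period.  The
    coefficient is

        r_c = sum sin(th_i - th_bar) sin(ph_i - ph_bar)
              / sqrt(sum sin^2(th_i - th_bar) * sum sin^2(ph_i - ph_bar))

    with circular means th_bar, ph_bar; the p-value comes from the
    asymptotic normal statistic z = r_c * sqrt(n * l20 * l02 / l22) where
    l_ij are the mixed sine moments.  Returns (r_c, p); both are NaN when
    either vector has zero circular dispersion.
    """
    x = np.asarray(phases_x, dtype=float)
    y = np.asarray(phases_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("phase vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 phase pairs")
    th = 2.0 * np.pi * x / period
    ph = 2.0 * np.pi * y / period
    th_bar = np.arctan2(np.mean(np.sin(th)), np.mean(np.cos(th)))
    ph_bar = np.arctan2(np.mean(np.sin(ph)), np.mean(np.cos(ph)))
    sx = np.sin(th - th_bar)
    sy = np.sin(ph - ph_bar)
    denom = np.sqrt(np.sum(sx**2) * np.sum(sy**2))
    if denom <= 1e-12:
        return float("nan"), float("nan")
    r_c = float(np.sum(sx * sy) / denom)
    l20 = np.mean(sx**2)
    l02 = np.mean(sy**2)
    l22 = np.mean(sx**2 * sy**2)
    if l22 <= 0:
        return r_c, float("nan")
    z = r_c * np.sqrt(n * l20 * l02 / l22)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return r_c, p


def amplitude_correlation(ra_x, ra_y):
    """Pearson correlation of relative amplitudes with a two-sided t-test p."""
    x = np.asarray(ra_x, dtype=float)
    y = np.asarray(ra_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("amplitude vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 amplitude pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def compare_platforms(
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    expr_a: ExpressionMatrix | None = None,
    expr_b: ExpressionMatrix | None = None,
    shared_times=None,
) -> CorrelationReport:
    """Full cross-platform report on the commonly rhythmic gene set.

    Phase and amplitude correlations use genes flagged significant in both
    rhythmicity tables; the expression correlation (when expression matrices
    are given) uses all common genes at the shared times.
    """
    common_sig = fits_a.index[fits_a["significant"]].intersection(
        fits_b.index[fits_b["significant"]]
    )
    n = len(common_sig)
    if n >= 3:
        circ_r, circ_p = circular_correlation(
            fits_a.loc[common_sig, "phase_h"], fits_b.loc[common_sig, "phase_h"]
        )
        amp_r, amp_p = amplitude_correlation(
            fits_a.loc[common_sig, "relamp"], fits_b.loc[common_sig, "relamp"]
        )
    else:
        circ_r = circ_p = amp_r = amp_p = float("nan")
    if expr_a is not None and expr_b is not None:
        mean_pearson = expression_correlation(expr_a, expr_b, shared_times)
    else:
        mean_pearson = float("nan")
    return CorrelationReport(
        mean_pearson=mean_pearson,
        circular_r=circ_r,
        circular_p=circ_p,
        amp_r=amp_r,
        amp_p=amp_p,
        n_genes=n,
    )
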