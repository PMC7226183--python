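"""Harmonic (cosinor) regression for 24-h rhythm detection.

The model for a single gene's abundance series y(t) on a positive linear
scale is

    y(t) = m + a*cos(omega*t) + b*sin(omega*t) + eps,   omega = 2*pi/period

fitted by ordinary least squares.  Amplitude A = sqrt(a^2 + b^2), relative
amplitude r_A = A/m, and the peak phase phi = (period/2pi)*atan2(b, a) mod
period, so the fitted curve equals m + A*cos(omega*(t - phi)).  Rhythmicity
is tested with the F statistic of the harmonic model against the
intercept-only model on (2, n-3) degrees of freedom; replicate samples at
equal times enter as independent observations.

`HarmonicRegression` is the statsmodels-style entry point for one series;
:func:`rhythmicity_table` fits every gene of a matrix at once and applies
Benjamini-Hochberg control with the significance rule q < q_cut and
r_A >= relamp_cut.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from circaweld.data import ExpressionMatrix
from circaweld.harmonize import ConcatenatedSeries

DEFAULT_PERIOD_H = 24.0
DEFAULT_Q_CUT = 0.05
DEFAULT_RELAMP_CUT = 0.1

_FIT_COLUMNS = [
    "mesor",
    "coef_cos",
    "coef_sin",
    "amplitude",
    "relamp",
    "phase_h",
    "pvalue",
]


def _design(t: np.ndarray, period: float) -> np.ndarray:
    omega = 2.0 * np.pi / period
    return np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])


def _check_times(t: np.ndarray, period: float) -> None:
    if len(t) < 6:
        raise ValueError("need at least 6 observations")
    distinct = np.unique(np.round(np.mod(t, period), 9))
    if len(distinct) < 3:
        raise ValueError(
            "model unidentifiable: fewer than 3 distinct times modulo the period"
        )


def _fit_matrix(Y: np.ndarray, t: np.ndarray, period: float):
    """Vectorized OLS cosinor fit of every row of Y against times t.

    Returns arrays (mesor, a, b, amplitude, relamp, phase, F, p).
    """
    X = _design(t, period)
    n = len(t)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # 3 x g
    fitted = X @ beta
    resid = Y.T - fitted
    rss1 = np.einsum("ij,ij->j", resid, resid)
    centered = Y.T - Y.T.mean(axis=0)
    rss0 = np.einsum("ij,ij->j", centered, centered)
    df_resid = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / 2.0) / (rss1 / df_resid)
    # constant series: rss0 == rss1 == 0 -> no evidence of rhythm
    F = np.where(rss0 <= 1e-300, 0.0, F)
    # numerically perfect harmonic fit: rss1 == 0 but rss0 > 0
    F = np.where((rss1 <= 1e-300) & (rss0 > 1e-300), np.inf, F)
    p = stats.f.sf(F, 2, df_resid)
    p = np.where(np.isinf(F), 0.0, p)

    mesor, a, b = beta
    amplitude = np.hypot(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        relamp = np.where(mesor > 0, amplitude / mesor, np.nan)
    phase = np.mod(period / (2.0 * np.pi) * np.arctan2(b, a), period)
    return mesor, a, b, amplitude, relamp, phase, F, p


class HarmonicRegression:
    """Cosinor model for a single abundance series.

    Parameters
    ----------
    endog
        Abundance values on a positive linear scale.
    times
        Observation times in hours; replicates at equal times allowed.
    period
        Oscillation period in hours (default 24).
    """

    def __init__(self, endog, times, period: float = DEFAULT_PERIOD_H):
        self.endog = np.asarray(endog, dtype=float)
        self.times = np.asarray(times, dtype=float)
        if self.endog.shape != self.times.shape:
            raise ValueError("endog and times must have equal length")
        _check_times(self.times, period)
        self.period = float(period)

    def fit(self, robust: bool = False) -> "HarmonicRegressionResults":
        """Fit by OLS; ``robust=True`` switches to IRLS with a bisquare norm."""
        if not robust:
            out = _fit_matrix(self.endog[None, :], self.times, self.period)
            mesor, a, b, amp, relamp, phase, F, p = (float(v[0]) for v in out)
            return HarmonicRegressionResults(
                self, mesor, a, b, F, p, robust=False
            )
        import statsmodels.api as sm

        X = _design(self.times, self.period)
        rlm = sm.RLM(self.endog, X, M=sm.robust.norms.TukeyBiweight()).fit()
        mesor, a, b = rlm.params
        # Wald test of (a, b) = 0 under the robust covariance
        cov = rlm.cov_params()[1:, 1:]
        ab = np.array([a, b])
        # pinv guards the degenerate perfect-fit case (robust scale 0)
        chi2 = float(ab @ np.linalg.pinv(cov) @ ab)
        p = float(stats.chi2.sf(chi2, 2)) if np.isfinite(chi2) else 0.0
        return HarmonicRegressionResults(
            self, float(mesor), float(a), float(b), chi2 / 2.0, p, robust=True
        )


class HarmonicRegressionResults:
    """Fitted cosinor parameters, rhythmicity test and summary table."""

    def __init__(self, model, mesor, coef_cos, coef_sin, fvalue, pvalue, robust):
        self.model = model
        self.mesor = mesor
        self.coef_cos = coef_cos
        self.coef_sin = coef_sin
        self.fvalue = fvalue
        self.pvalue = pvalue
        self.robust = robust
        self.nobs = len(model.endog)
        self.df_resid = self.nobs - 3

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.coef_cos, self.coef_sin))

    @property
    def relative_amplitude(self) -> float:
        if self.mesor <= 0:
            return float("nan")
        return self.amplitude / self.mesor

    @property
    def phase_h(self) -> float:
        """Hours after synchronization at which the fitted cosine peaks."""
        return float(
            np.mod(
                self.model.period
                / (2.0 * np.pi)
                * np.arctan2(self.coef_sin, self.coef_cos),
                self.model.period,
            )
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return _design(self.model.times, self.model.period) @ np.array(
            [self.mesor, self.coef_cos, self.coef_sin]
        )

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def predict(self, times) -> np.ndarray:
        return _design(np.asarray(times, dtype=float), self.model.period) @ np.array(
            [self.mesor, self.coef_cos, self.coef_sin]
        )

    def summary(self) -> str:
        kind = "IRLS (bisquare)" if self.robust else "OLS"
        stat = "Wald chi2/2" if self.robust else "F(2, %d)" % self.df_resid
        lines = [
            "Harmonic (cosinor) regression results",
            "=" * 46,
            f"Method:              {kind}",
            f"Period (h):          {self.model.period:g}",
            f"No. observations:    {self.nobs}",
            f"Mesor:               {self.mesor:.6g}",
            f"Amplitude:           {self.amplitude:.6g}",
            f"Relative amplitude:  {self.relative_amplitude:.6g}",
            f"Peak phase (h):      {self.phase_h:.6g}",
            f"{stat + ':':<21}{self.fvalue:.6g}",
            f"p-value:             {self.pvalue:.6g}",
            "=" * 46,
        ]
        return "\n".join(lines)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rhythmicity_table(
    data: ExpressionMatrix | ConcatenatedSeries,
    period: float = DEFAULT_PERIOD_H,
    q_cut: float = DEFAULT_Q_CUT,
    relamp_cut: float = DEFAULT_RELAMP_CUT,
) -> pd.DataFrame:
    """Fit the cosinor model to every gene and flag significant rhythms.

    Input must be on a linear (or linear-normalized) scale; q-values come
    from BH adjustment over all tested genes, and a gene is significant iff
    q < q_cut and its relative amplitude is >= relamp_cut.  Output is sorted
    by (qvalue, gene_id).
    """
    matrix = data.matrix if isinstance(data, ConcatenatedSeries) else data
    if matrix.is_log_scale:
        raise ValueError(
            f"matrix is on a log scale ({matrix.scale}); de-log (2**x) before fitting"
        )
    t = matrix.sample_time_h.to_numpy()
    _check_times(t, period)
    Y = matrix.values.to_numpy(dtype=float)
    mesor, a, b, amp, relamp, phase, F, p = _fit_matrix(Y, t, period)
    q = bh_adjust(p)
    significant = (q < q_cut) & (relamp >= relamp_cut) & np.isfinite(relamp)
    table = pd.DataFrame(
        {
            "mesor": mesor,
            "coef_cos": a,
            "coef_sin": b,
            "amplitude": amp,
            "relamp": relamp,
            "phase_h": phase,
            "pvalue": p,
            "qvalue": q,
            "significant": significant,
        },
        index=matrix.gene_ids.copy(),
    )
    table.index.name = "gene_id"
    return table.sort_values(["qvalue", "gene_id"], kind="stable")


def write_fits(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_fits(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    table["significant"] = table["significant"].astype(bool)
    return table
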