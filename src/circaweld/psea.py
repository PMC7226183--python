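"""Phase Set Enrichment Analysis (PSEA).

Tests, per gene set, whether the peak phases of its significantly rhythmic
members cluster on the 24-h circle, using the Kuiper test against a uniform
background.  Phases are rounded to the full hour before testing, sets with
fewer than ``min_genes`` rhythmic members are excluded, p-values are BH
adjusted across the tested sets, and each tested set gets a vector-average
(circular mean) phase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from circaweld.data import GeneSetCollection
from circaweld.rhythm import bh_adjust

PERIOD_H = 24.0


def kuiper_statistic(u) -> float:
    """Kuiper V = D+ + D- of values in [0, 1) against the uniform law.

    D+ = max_i(i/n - u_(i)), D- = max_i(u_(i) - (i-1)/n) over the sorted
    sample; V is invariant under rotation of the circle [0, 1).
    """
    u = np.sort(np.asarray(u, dtype=float))
    n = len(u)
    if n < 1:
        raise ValueError("need at least one value")
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("values must lie in [0, 1)")
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    return float(d_plus + d_minus)


def kuiper_pvalue(V: float, n: int) -> float:
    """Asymptotic upper-tail p of the Kuiper statistic with Stephens' correction.

    lambda = (sqrt(n) + 0.155 + 0.24/sqrt(n)) * V and
    p = 2 * sum_{j>=1} (4 j^2 lambda^2 - 1) exp(-2 j^2 lambda^2), the series
    truncated once terms fall below 1e-12; the result is clamped to [0, 1].
    Intended for n >= 8; still applied for smaller n down to 5.
    """
    if not 0.0 <= V <= 1.0:
        raise ValueError("V must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    lam = (np.sqrt(n) + 0.155 + 0.24 / np.sqrt(n)) * V
    if lam < 1e-6:
        return 1.0
    total = 0.0
    for j in range(1, 1001):
        term = (4.0 * j**2 * lam**2 - 1.0) * np.exp(-2.0 * j**2 * lam**2)
        total += term
        if abs(term) < 1e-12:
            break
    return float(min(max(2.0 * total, 0.0), 1.0))


def circular_mean_phase(phases, period: float = PERIOD_H) -> float:
    """Vector-average phase in hours, in [0, period).

    NaN when the resultant vector length vanishes (perfectly balanced
    phases, e.g. two antipodal points).
    """
    ph = np.asarray(phases, dtype=float)
    if len(ph) == 0:
        raise ValueError("need at least one phase")
    ang = 2.0 * np.pi * ph / period
    c, s = np.mean(np.cos(ang)), np.mean(np.sin(ang))
    if np.hypot(c, s) <= 1e-9:
        return float("nan")
    h = float(np.mod(np.arctan2(s, c) * period / (2.0 * np.pi), period))
    return 0.0 if period - h < 1e-9 else h


def _round_phase_full_hour(phase: np.ndarray, period: float = PERIOD_H) -> np.ndarray:
    """Round to the nearest full hour, half away from zero, with 24 -> 0."""
    rounded = np.floor(phase + 0.5)  # phases are non-negative
    return np.mod(rounded, period)


def run_psea(
    fits: pd.DataFrame,
    sets: GeneSetCollection,
    min_genes: int = 5,
    q_cut: float = 0.05,
    round_phase: bool = True,
) -> pd.DataFrame:
    """Phase set enrichment over a rhythmicity table.

    For each set the phases of its significantly rhythmic members (rounded
    to the full hour when ``round_phase``) are Kuiper-tested against the
    uniform circle; sets with fewer than ``min_genes`` rhythmic members are
    reported untested.  q-values are BH adjusted across tested sets only and
    a set is enriched iff q < q_cut.  ``mean_phase_h`` is the circular mean
    of the unrounded phases.
    """
    if len(sets) == 0:
        raise ValueError("empty gene set collection")
    sig = fits[fits["significant"]]
    rows = []
    for name, members in sets:
        present = sig.index.intersection(members)
        n = len(present)
        phases = sig.loc[present, "phase_h"].to_numpy()
        tested = n >= min_genes
        if tested:
            test_phases = _round_phase_full_hour(phases) if round_phase else phases
            V = kuiper_statistic(test_phases / PERIOD_H)
            p = kuiper_pvalue(V, n)
            mean_phase = circular_mean_phase(phases)
        else:
            V = p = float("nan")
            mean_phase = circular_mean_phase(phases) if n else float("nan")
        rows.append(
            {
                "set_name": name,
                "n_rhythmic": n,
                "kuiper_V": V,
                "pvalue": p,
                "mean_phase_h": mean_phase,
                "tested": tested,
            }
        )
    table = pd.DataFrame(rows).set_index("set_name")
    table["qvalue"] = np.nan
    mask = table["tested"]
    if mask.any():
        table.loc[mask, "qvalue"] = bh_adjust(table.loc[mask, "pvalue"].to_numpy())
    table["enriched"] = (table["qvalue"] < q_cut).fillna(False)
    return table.sort_values(["qvalue", "set_name"], kind="stable")


def write_psea(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
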