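import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import circaweld as cw
from circaweld.data import ExpressionMatrix
from circaweld.rhythm import rhythmicity_table

T_CONCAT = np.arange(0.0, 42.1, 3.0)


def cosine(t, mesor, relamp, phase):
    return mesor * (1 + relamp * np.cos(2 * np.pi * (t - phase) / 24.0))


def oracle_fit(y, t, period=24.0):
    """Brute-force cosinor oracle: explicit 3x3 normal equations and the
    F distribution, independent of the package's lstsq path."""
    w = 2 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    F = ((rss0 - rss1) / 2) / (rss1 / (len(t) - 3))
    p = float(stats.f.sf(F, 2, len(t) - 3))
    m, a, b = beta
    return m, float(np.hypot(a, b)), float(np.mod(period / (2 * np.pi) * np.arctan2(b, a), period)), p


class TestHarmonicRegression:
    def test_noiseless_model_recovered_exactly(self):
        y = cosine(T_CONCAT, 10.0, 0.3, 8.0)
        res = cw.HarmonicRegression(y, T_CONCAT).fit()
        assert res.mesor == pytest.approx(10.0, rel=1e-9)
        assert res.amplitude == pytest.approx(3.0, rel=1e-9)
        assert res.relative_amplitude == pytest.approx(0.3, rel=1e-9)
        assert res.phase_h == pytest.approx(8.0, rel=1e-9)
        assert res.pvalue < 1e-12

    def test_constant_series_is_null(self):
        res = cw.HarmonicRegression(np.full_like(T_CONCAT, 5.0), T_CONCAT).fit()
        assert res.amplitude == pytest.approx(0.0, abs=1e-12)
        assert res.relative_amplitude == pytest.approx(0.0, abs=1e-12)
        assert res.fvalue == 0.0
        assert res.pvalue == 1.0

    def test_noisy_fit_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        y = cosine(T_CONCAT, 10.0, 0.2, 0.0) + rng.normal(0, 0.1, len(T_CONCAT))
        res = cw.HarmonicRegression(y, T_CONCAT).fit()
        m, A, phi, p = oracle_fit(y, T_CONCAT)
        assert res.mesor == pytest.approx(m, abs=1e-10)
        assert res.amplitude == pytest.approx(A, abs=1e-10)
        assert res.phase_h == pytest.approx(phi, abs=1e-10)
        assert res.pvalue == pytest.approx(p, abs=1e-10)
        # parameters within 3 sd of truth for this fixed seed
        assert abs(res.mesor - 10.0) < 3 * 0.1
        assert abs(res.amplitude - 2.0) < 3 * 0.1

    def test_pvalues_match_oracle_on_many_random_series(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            y = rng.normal(10, 1, len(T_CONCAT))
            res = cw.HarmonicRegression(y, T_CONCAT).fit()
            assert res.pvalue == pytest.approx(oracle_fit(y, T_CONCAT)[3], abs=1e-10)

    def test_too_few_distinct_circadian_times_rejected(self):
        t = np.array([0.0, 12.0, 24.0, 36.0, 48.0, 60.0])  # 2 distinct mod 24
        with pytest.raises(ValueError, match="unidentifiable"):
            cw.HarmonicRegression(np.ones(6), t)
        with pytest.raises(ValueError, match="at least 6"):
            cw.HarmonicRegression(np.ones(4), np.arange(4.0))

    def test_summary_and_prediction(self):
        y = cosine(T_CONCAT, 10.0, 0.3, 8.0)
        res = cw.HarmonicRegression(y, T_CONCAT).fit()
        text = res.summary()
        assert "Mesor" in text and "Peak phase" in text
        assert np.allclose(res.predict(T_CONCAT), y, atol=1e-9)
        assert np.allclose(res.resid, 0.0, atol=1e-9)

    def test_robust_mode_resists_outlier(self):
        rng = np.random.default_rng(8)
        y = cosine(T_CONCAT, 10.0, 0.3, 8.0) + rng.normal(0, 0.05, len(T_CONCAT))
        y_out = y.copy()
        y_out[3] += 25.0
        plain = cw.HarmonicRegression(y_out, T_CONCAT).fit()
        robust = cw.HarmonicRegression(y_out, T_CONCAT).fit(robust=True)
        assert abs(robust.phase_h - 8.0) < abs(plain.phase_h - 8.0)
        assert robust.relative_amplitude == pytest.approx(0.3, rel=0.05)

    @settings(max_examples=25, deadline=None)
    @given(
        delta=st.floats(0.0, 48.0),
        phase=st.floats(0.0, 23.9),
        scale=st.floats(0.1, 100.0),
    )
    def test_phase_and_scale_equivariance(self, delta, phase, scale):
        """Shifting time shifts phase mod 24; scaling y scales mesor and
        amplitude but leaves relamp, phase and p unchanged."""
        y = cosine(T_CONCAT, 10.0, 0.4, phase) + 0.01 * np.sin(T_CONCAT)
        base = cw.HarmonicRegression(y, T_CONCAT).fit()
        shifted = cw.HarmonicRegression(y, T_CONCAT + delta).fit()
        diff = (shifted.phase_h - base.phase_h - delta) % 24.0
        assert min(diff, 24.0 - diff) < 1e-6
        scaled = cw.HarmonicRegression(scale * y, T_CONCAT).fit()
        assert scaled.mesor == pytest.approx(scale * base.mesor, rel=1e-9)
        assert scaled.amplitude == pytest.approx(scale * base.amplitude, rel=1e-9)
        assert scaled.relative_amplitude == pytest.approx(base.relative_amplitude, rel=1e-9)
        assert scaled.phase_h == pytest.approx(base.phase_h, abs=1e-6)
        assert scaled.pvalue == pytest.approx(base.pvalue, rel=1e-6)


class TestBHAdjust:
    def test_hand_worked_stepup(self):
        assert np.allclose(cw.bh_adjust([0.005, 0.5]), [0.01, 0.5])

    def test_equal_pvalues_unchanged(self):
        assert np.allclose(cw.bh_adjust([0.04] * 4), [0.04] * 4)

    def test_single_pvalue_identity(self):
        assert cw.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_manual_stepup_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        # independent step-up evaluation
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(cw.bh_adjust(p), q, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            cw.bh_adjust([0.5, 1.5])


class TestRhythmicityTable:
    def _matrix(self, Y, t, scale="linear"):
        df = pd.DataFrame(Y, columns=[f"s{j}" for j in range(Y.shape[1])])
        df.index = pd.Index([f"g{i}" for i in range(Y.shape[0])], name="gene_id")
        return ExpressionMatrix(df, pd.Series(t, index=df.columns), "x", scale)

    def test_log_scale_rejected_with_delog_hint(self, small_platforms):
        intensity, _ = small_platforms
        with pytest.raises(ValueError, match="de-log"):
            rhythmicity_table(intensity)

    def test_relamp_filter_blocks_tiny_amplitudes(self):
        t = T_CONCAT
        Y = np.vstack(
            [cosine(t, 10.0, 0.05, 4.0)] + [cosine(t, 10.0, 0.4, h) for h in range(8)]
        )
        table = rhythmicity_table(self._matrix(Y, t))
        assert table.loc["g0", "pvalue"] < 1e-10
        assert not table.loc["g0", "significant"]
        assert table.loc["g1":"g8", "significant"].all() or table["significant"].sum() == 8

    def test_mesor_nonpositive_flagged_nonsignificant(self):
        t = T_CONCAT
        Y = np.vstack([cosine(t, 10.0, 0.4, 4.0) - 10.0])  # zero mesor
        table = rhythmicity_table(self._matrix(Y, t))
        assert not table["significant"].iloc[0]

    def test_output_sorted_by_q_then_gene(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(10, 1, (50, len(T_CONCAT)))
        table = rhythmicity_table(self._matrix(Y, T_CONCAT))
        key = list(zip(table["qvalue"], table.index))
        assert key == sorted(key)

    def test_fits_tsv_roundtrip(self, tmp_path):
        Y = np.vstack([cosine(T_CONCAT, 10.0, 0.4, h) for h in range(5)])
        table = rhythmicity_table(self._matrix(Y, T_CONCAT))
        from circaweld.rhythm import write_fits, read_fits

        write_fits(table, tmp_path / "f.tsv")
        back = read_fits(tmp_path / "f.tsv")
        pd.testing.assert_frame_equal(back, table)
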