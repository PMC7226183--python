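import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import circaweld as cw
from circaweld.data import ExpressionMatrix
from circaweld.preprocess import cpm, preprocess_counts, read_feature_map


def _counts(values, times=None):
    df = pd.DataFrame(values)
    df.index = [f"g{i}" for i in range(len(df))]
    df.index.name = "gene_id"
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    if times is None:
        times = np.arange(df.shape[1], dtype=float) * 3
    return ExpressionMatrix(df, pd.Series(times, index=df.columns), "rnaseq", "counts")


class TestCollapseFeatures:
    def test_highest_mean_feature_represents_gene(self):
        df = pd.DataFrame(
            {"s0": [4.0, 8.0], "s1": [6.0, 6.0]}, index=["f1", "f2"]
        )  # means 5.0 and 7.0
        m = ExpressionMatrix(df, pd.Series([0.0, 3.0], index=df.columns), "p", "linear")
        out = cw.collapse_features(m, {"f1": "G", "f2": "G"})
        assert list(out.gene_ids) == ["G"]
        assert np.allclose(out.values.loc["G"], df.loc["f2"])

    def test_one_feature_per_gene_is_identity_up_to_renaming(self):
        df = pd.DataFrame({"s0": [1.0, 2.0], "s1": [3.0, 4.0]}, index=["f1", "f2"])
        m = ExpressionMatrix(df, pd.Series([0.0, 3.0], index=df.columns), "p", "linear")
        out = cw.collapse_features(m, {"f1": "A", "f2": "B"})
        assert np.allclose(out.values.to_numpy(), df.to_numpy())
        assert list(out.gene_ids) == ["A", "B"]

    def test_tie_breaks_to_smallest_feature_id(self):
        # exhaustive check on a 3-feature toy: f2 and f3 tie above f1
        df = pd.DataFrame(
            {"s0": [1.0, 5.0, 5.0], "s1": [1.0, 5.0, 5.0]}, index=["f1", "f3", "f2"]
        )
        m = ExpressionMatrix(df, pd.Series([0.0, 3.0], index=df.columns), "p", "linear")
        out = cw.collapse_features(m, {"f1": "G", "f2": "G", "f3": "G"})
        winner_means = {f: df.loc[f].mean() for f in ["f1", "f2", "f3"]}
        best = min(f for f, v in winner_means.items() if v == max(winner_means.values()))
        assert best == "f2"
        assert np.allclose(out.values.loc["G"], df.loc[best])

    def test_unmapped_features_dropped_and_empty_map_rejected(self):
        df = pd.DataFrame({"s0": [1.0, 2.0], "s1": [1.0, 2.0]}, index=["f1", "f2"])
        m = ExpressionMatrix(df, pd.Series([0.0, 3.0], index=df.columns), "p", "linear")
        out = cw.collapse_features(m, {"f1": "A"})
        assert list(out.gene_ids) == ["A"]
        with pytest.raises(ValueError, match="empty"):
            cw.collapse_features(m, {})

    def test_map_reader(self, tmp_path):
        (tmp_path / "map.tsv").write_text("f1\tA\nf2\tB\n")
        assert read_feature_map(tmp_path / "map.tsv") == {"f1": "A", "f2": "B"}


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        m = _counts([[10, 10], [20, 20], [30, 30]])
        nf = cw.tmm_factors(m)
        assert np.allclose(nf.factor_per_sample, 1.0)

    def test_pure_depth_shift_is_normalized_away(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 5000, size=300)
        m = _counts(np.column_stack([base, 2 * base, base]))
        nf = cw.tmm_factors(m)
        normed = cpm(m, nf)
        # sample 1 is sample 0 at double depth: identical after CPM with factors
        assert np.allclose(normed.values["s0"], normed.values["s1"], rtol=1e-9)

    def test_factors_have_geometric_mean_one(self, small_platforms):
        _, counts = small_platforms
        nf = cw.tmm_factors(counts)
        assert abs(np.log(nf.factor_per_sample).mean()) < 1e-9

    def test_rejects_all_zero_sample(self):
        m = _counts([[0, 5], [0, 7], [0, 9]])
        with pytest.raises(ValueError, match="all-zero.*s0"):
            cw.tmm_factors(m)

    def test_matches_edger_reference(self, tmp_path, small_platforms):
        """Cross-check TMM factors against Bioconductor edgeR on real-ish data."""
        _, counts = small_platforms
        sub = counts.values.iloc[:400]
        sub.to_csv(tmp_path / "counts.tsv", sep="\t")
        script = textwrap.dedent("""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("{d}/counts.tsv", row.names=1))
            f <- calcNormFactors(DGEList(counts=x), method="TMM")$samples$norm.factors
            write(paste(f, collapse="\\t"), "{d}/factors.txt")
        """).format(d=tmp_path)
        (tmp_path / "tmm.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", str(tmp_path / "tmm.R")], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        ref = np.loadtxt(tmp_path / "factors.txt")
        sub_m = ExpressionMatrix(
            sub, counts.sample_time_h, counts.platform, "counts"
        )
        ours = cw.tmm_factors(sub_m).factor_per_sample.to_numpy()
        assert np.allclose(ours, ref, rtol=1e-6)


class TestCPM:
    def test_log_cpm_closed_form(self):
        m = _counts([[1000], [999000]], times=[0.0])
        # single sample not enough for TMM; use unit factors (factors=None)
        out = cpm(m, None, prior_count=0.0, log=True)
        assert out.values.iloc[0, 0] == pytest.approx(np.log2(1000.0), abs=1e-12)

    def test_zero_count_with_prior_is_finite(self):
        m = _counts([[0, 0], [100, 100]])
        out = cw.log_cpm(m, None, prior_count=0.5)
        assert np.isfinite(out.values.to_numpy()).all()

    def test_doubling_counts_and_library_leaves_cpm_unchanged(self):
        m1 = _counts([[10, 10], [90, 90]])
        m2 = _counts([[20, 20], [180, 180]])
        a = cpm(m1, None, prior_count=0.0, log=True)
        b = cpm(m2, None, prior_count=0.0, log=True)
        assert np.allclose(a.values, b.values)

    def test_negative_prior_rejected(self):
        with pytest.raises(ValueError, match="prior"):
            cw.log_cpm(_counts([[1, 1]] * 6), None, prior_count=-1)

    def test_column_sums_of_delogged_cpm_are_one_million(self, small_platforms):
        _, counts = small_platforms
        out = cpm(counts, None, prior_count=0.0, log=True)
        sums = (2.0 ** out.values).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-3)


class TestFilterExpressed:
    def test_boundary_inclusive_on_mean_cpm(self):
        # three genes with mean CPM 0.4 / 0.5 / 0.6 in a fixed library
        lib = 1e6
        base = np.array([[396, 404], [500, 500], [610, 590]]) // 1  # means 400/500/600
        filler = np.full((1, 2), int(lib) - base.sum(axis=0).max())
        m = _counts(np.vstack([base, filler]) )
        mean_cpm = cpm(m, cw.tmm_factors(m)).values.mean(axis=1)
        out = cw.filter_expressed(m, cutoff=float(mean_cpm.iloc[1]))
        assert "g0" not in out.gene_ids and {"g1", "g2"} <= set(out.gene_ids)

    def test_minus_infinity_cutoff_is_identity(self, small_platforms):
        intensity, _ = small_platforms
        out = cw.filter_expressed(intensity, -np.inf)
        pd.testing.assert_frame_equal(out.values, intensity.values)

    def test_intensity_mean_rule(self):
        df = pd.DataFrame(
            {"s0": [2.0, 3.0, 5.0], "s1": [2.0, 3.0, 5.0]},
            index=["low", "edge", "high"],
        )
        m = ExpressionMatrix(
            df, pd.Series([0.0, 3.0], index=df.columns), "p", "log2-intensity"
        )
        out = cw.filter_expressed(m, 3.0)
        assert list(out.gene_ids) == ["edge", "high"]  # "at least" is inclusive

    def test_filter_removing_everything_rejected(self, small_platforms):
        intensity, _ = small_platforms
        with pytest.raises(ValueError, match="removes all"):
            cw.filter_expressed(intensity, 1e9)

    def test_renormalized_filter_is_stable_over_seeds(self):
        """A second filter pass after renormalization removes (almost) no
        further genes across seeded synthetic datasets."""
        unstable = 0
        for seed in range(20):
            truth = cw.simulate_truth(400, 0.2, seed=seed, baseline_mean_log2=4.0)
            counts = cw.render_counts(truth, seed=seed)
            first = cw.filter_expressed(counts, 0.5)
            second = cw.filter_expressed(first, 0.5)
            if second.n_genes != first.n_genes:
                unstable += 1
        assert unstable <= 1  # >= 95% of datasets are stable

    def test_preprocess_counts_returns_consistent_bundle(self, small_platforms):
        _, counts = small_platforms
        logcpm, lincpm, factors = preprocess_counts(counts, 0.5)
        assert logcpm.scale == "log2-cpm" and lincpm.scale == "linear"
        assert list(logcpm.gene_ids) == list(lincpm.gene_ids)
        assert abs(np.log(factors.factor_per_sample).mean()) < 1e-9
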