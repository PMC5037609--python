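"""NB differential pipeline: counting, size factors, dispersions, Wald
test, BH, and calls."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enhancerdiff import differential as diff
from enhancerdiff.candidates import standardize_peaks
from enhancerdiff.core import GenomicInterval, PeakRecord, ValidationError

SIZES = {"chrT": 100_000}


def make_cm(array, conds):
    arr = np.asarray(array)
    cols = [f"s{i}" for i in range(arr.shape[1])]
    counts = pd.DataFrame(
        arr, columns=cols, index=[f"r{i}" for i in range(arr.shape[0])]
    )
    return diff.CountMatrix(counts, pd.Series(dict(zip(cols, conds))))


class TestCountInWindows:
    def windows_at(self, *summits):
        peaks = [
            PeakRecord(
                interval=GenomicInterval("chrT", s - 250, s + 251),
                name=f"p{s}",
                score=5.0,
                summit=s,
                enrichment=5.0,
            )
            for s in summits
        ]
        return standardize_peaks(peaks, SIZES)

    def window_at(self, summit):
        return self.windows_at(summit)

    def frags(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_overlap_counting(self):
        w = self.window_at(10_000)  # window [9500, 10500)
        frags = self.frags(
            [
                ("chrT", 9400, 9600),  # overlaps
                ("chrT", 10_499, 10_600),  # 1 bp overlap
                ("chrT", 9000, 9100),  # disjoint
                ("chrT", 9900, 10_100),  # contained
            ]
        )
        cm = diff.count_in_windows(
            {"a": frags, "b": frags}, w, {"a": "A", "b": "B"}
        )
        assert cm.counts.iloc[0, 0] == 3

    def test_abutting_fragment_not_counted(self):
        w = self.window_at(10_000)
        frags = self.frags([("chrT", 10_500, 10_700), ("chrT", 9300, 9500)])
        cm = diff.count_in_windows(
            {"a": frags, "b": frags}, w, {"a": "A", "b": "B"}
        )
        assert cm.counts.iloc[0, 0] == 0

    def test_fragment_spanning_two_windows_counts_in_both(self):
        w = self.windows_at(10_000, 11_000)
        frags = self.frags([("chrT", 10_400, 10_600)])
        cm = diff.count_in_windows(
            {"a": frags, "b": frags}, w, {"a": "A", "b": "B"}
        )
        assert list(cm.counts["a"]) == [1, 1]

    def test_zero_fragment_sample_rejected(self):
        w = self.window_at(10_000)
        with pytest.raises(ValidationError, match="zero fragments"):
            diff.count_in_windows(
                {"a": self.frags([]), "b": self.frags([("chrT", 1, 2)])},
                w,
                {"a": "A", "b": "B"},
            )


class TestSizeFactors:
    def test_proportional_columns(self):
        """Column 2 = 2x column 1 exactly -> factors (1/sqrt(2), sqrt(2))."""
        c1 = np.array([10, 50, 100, 7, 3])
        counts = pd.DataFrame({"a": c1, "b": 2 * c1})
        sf = diff.estimate_size_factors(counts)
        np.testing.assert_allclose(sf.values, [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_columns(self):
        c = np.array([10, 50, 100])
        sf = diff.estimate_size_factors(pd.DataFrame({"a": c, "b": c, "c": c}))
        np.testing.assert_allclose(sf.values, 1.0)

    def test_single_region(self):
        sf = diff.estimate_size_factors(pd.DataFrame({"a": [4], "b": [16]}))
        np.testing.assert_allclose(sf.values, [0.5, 2.0])

    def test_fallback_total_count(self):
        counts = pd.DataFrame({"a": [4, 0], "b": [0, 8]})
        with pytest.warns(UserWarning, match="total-count"):
            sf = diff.estimate_size_factors(counts)
        np.testing.assert_allclose(sf.values[0] * sf.values[1], 1.0)
        assert sf.values[1] / sf.values[0] == 2.0


class TestDispersions:
    def test_poisson_counts_yield_near_zero(self):
        rng = np.random.default_rng(0)
        cm = make_cm(rng.poisson(100, size=(1000, 6)), ["A"] * 3 + ["B"] * 3)
        sf = diff.estimate_size_factors(cm.counts)
        disp = diff.estimate_dispersions(cm, sf)
        assert disp.median() <= 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        alpha, mu = 0.1, 100.0
        g = rng.gamma(1 / alpha, alpha, size=(2000, 6))
        cm = make_cm(rng.poisson(mu * g), ["A"] * 3 + ["B"] * 3)
        sf = diff.estimate_size_factors(cm.counts)
        disp = diff.estimate_dispersions(cm, sf)
        assert 0.05 <= disp.median() <= 0.2

    def test_constant_counts_floor_at_trend(self):
        """Zero observed variance cannot push dispersion below the trend
        (a pure-noise downward deviation)."""
        rng = np.random.default_rng(2)
        arr = rng.poisson(100, size=(500, 4))
        arr[0] = 100  # exactly constant row
        cm = make_cm(arr, ["A", "A", "B", "B"])
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = diff.estimate_dispersions(cm, sf)
        assert np.isfinite(disp.iloc[0])
        assert disp.iloc[0] <= disp.median() * 1.5

    def test_all_zero_region_untestable(self):
        arr = np.vstack([[0, 0, 0, 0], np.full((50, 4), 20)])
        cm = make_cm(arr, ["A", "A", "B", "B"])
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = diff.estimate_dispersions(cm, sf)
        assert np.isnan(disp.iloc[0])


class TestWaldTest:
    def test_identical_means_null(self):
        arr = np.tile([50, 50, 50, 50], (5, 1))
        cm = make_cm(arr, ["A", "A", "B", "B"])
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = pd.Series(0.05, index=cm.counts.index)
        res = diff.wald_test(cm, sf, disp, "A", "B")
        np.testing.assert_allclose(res["log2fc"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_poisson_score_limit(self):
        """With alpha -> 0 and large counts, the Wald z^2 approaches the
        Poisson score statistic on the same data (within 5%)."""
        rng = np.random.default_rng(3)
        a = rng.poisson(1000, size=(200, 3))
        b = rng.poisson(1200, size=(200, 3))
        cm = make_cm(np.hstack([a, b]), ["A"] * 3 + ["B"] * 3)
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = pd.Series(0.0, index=cm.counts.index)
        res = diff.wald_test(cm, sf, disp, "A", "B")
        mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
        # Poisson score statistic for H0: lambda_a = lambda_b with equal n
        pooled = (a.sum(axis=1) + b.sum(axis=1)) / 6
        score = (3 * (mu_a - pooled) ** 2 + 3 * (mu_b - pooled) ** 2) / pooled
        z2 = (res["log2fc"] / res["se"]) ** 2
        ratio = z2.to_numpy() / score
        assert np.median(np.abs(ratio - 1)) < 0.05

    def test_zero_condition_mean_pseudocount(self):
        arr = np.array([[0, 0, 40, 40]])
        cm = make_cm(arr, ["A", "A", "B", "B"])
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = pd.Series(0.05, index=cm.counts.index)
        res = diff.wald_test(cm, sf, disp, "A", "B")
        assert np.isfinite(res["log2fc"].iloc[0])
        np.testing.assert_allclose(res["log2fc"].iloc[0], np.log2(0.5 / 40.5))

    def test_monotonicity_in_treatment_counts(self):
        base = np.array([[100, 100, 100, 100]])
        sf = pd.Series(1.0, index=["s0", "s1", "s2", "s3"])
        disp_val = 0.05
        prev = -np.inf
        for bump in (0, 20, 50, 100):
            arr = base.copy()
            arr[0, :2] += bump
            cm = make_cm(arr, ["A", "A", "B", "B"])
            disp = pd.Series(disp_val, index=cm.counts.index)
            res = diff.wald_test(cm, sf, disp, "A", "B")
            assert res["log2fc"].iloc[0] >= prev
            prev = res["log2fc"].iloc[0]


def brute_force_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(m * p[order[j - 1]] / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


class TestBH:
    def test_hand_example(self):
        q = diff.adjust_bh(np.array([0.005, 0.01, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_single_p(self):
        np.testing.assert_allclose(diff.adjust_bh(np.array([0.03])), [0.03])

    def test_all_equal(self):
        q = diff.adjust_bh(np.full(7, 0.2))
        np.testing.assert_allclose(q, 0.2)

    def test_nan_preserved_and_excluded_from_m(self):
        q = diff.adjust_bh(np.array([0.01, np.nan, 0.02]))
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.02])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(diff.adjust_bh(p), brute_force_bh(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.random(500)
        np.testing.assert_allclose(
            diff.adjust_bh(p), multipletests(p, method="fdr_bh")[1]
        )


class TestCalls:
    def make_results(self, q, lfc):
        return pd.DataFrame({"q": q, "log2fc": lfc})

    def test_me_dee_and_nondiff(self):
        res = self.make_results([0.001, 0.5, 0.005], [1.2, 3.0, -2.0])
        calls = diff.call_enhancers(res)
        assert list(calls) == ["ME", "non_differential", "DEE"]

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(6)
        g = rng.gamma(20, 0.05, size=(300, 5))
        arr = rng.poisson(100 * g)
        arr[:50, :3] *= 3
        cm = make_cm(arr, ["A", "A", "A", "B", "B"])
        res_ab = diff.differential_analysis(cm, "A", "B")
        res_ba = diff.differential_analysis(cm, "B", "A")
        np.testing.assert_allclose(
            res_ab["log2fc"], -res_ba["log2fc"], rtol=1e-10
        )
        swapped = res_ba["call"].map(
            {"ME": "DEE", "DEE": "ME", "non_differential": "non_differential"}
        )
        assert (res_ab["call"] == swapped).all()


class TestRecoveryAndCalibration:
    def test_planted_threefold_recovery(self, small_dataset):
        """On the small synthetic dataset, planted 3-fold differentials
        are recovered with high sensitivity and controlled FDR."""
        from enhancerdiff.pipeline import Pipeline, inputs_from_synthetic, recovery_metrics

        pipe = Pipeline(inputs_from_synthetic(small_dataset, with_tf_tracks=False))
        pipe.run(["candidates", "counts", "differential"])
        m = recovery_metrics(
            small_dataset, pipe.results["candidates"], pipe.results["differential"]
        )
        assert m["sensitivity"] >= 0.85  # 40 planted enhancers at this scale
        assert m["fdr"] <= 0.05

    def test_pydeseq2_cross_check(self):
        """Independent NB implementation agrees on fold changes and on
        which regions are strongly differential."""
        import warnings

        rng = np.random.default_rng(7)
        g = rng.gamma(20, 0.05, size=(300, 6))
        arr = rng.poisson(120 * g)
        arr[:60, :3] *= 3
        cm = make_cm(arr, ["A"] * 3 + ["B"] * 3)
        res = diff.differential_analysis(cm, "A", "B")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from pydeseq2.dds import DeseqDataSet
            from pydeseq2.ds import DeseqStats

            meta = pd.DataFrame(
                {"condition": ["A"] * 3 + ["B"] * 3}, index=cm.counts.columns
            )
            dds = DeseqDataSet(
                counts=cm.counts.T, metadata=meta, design="~condition", quiet=True
            )
            dds.deseq2()
            ds = DeseqStats(
                dds, contrast=["condition", "A", "B"], quiet=True
            )
            ds.summary()
            ref = ds.results_df

        r = np.corrcoef(res["log2fc"], ref["log2FoldChange"])[0, 1]
        assert r > 0.95
        ours = set(res.index[res["q"] < 0.01])
        theirs = set(ref.index[ref["padj"] < 0.01])
        overlap = len(ours & theirs) / max(len(ours | theirs), 1)
        assert overlap > 0.8
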