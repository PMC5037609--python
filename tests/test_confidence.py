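"""TF occupancy at enhancers, annotation overlap tests, and the
confidence-group cascade."""
import numpy as np
import pytest
from scipy import stats

from enhancerdiff import confidence as conf
from enhancerdiff import coverage as cov
from enhancerdiff.candidates import standardize_peaks
from enhancerdiff.core import (
    ExpressionRecord,
    GenomicInterval,
    PeakRecord,
    ValidationError,
)

SIZES = {"chrT": 50_000}
PAIR = ("T", "G")


def region_at(summit):
    peak = PeakRecord(
        interval=GenomicInterval("chrT", summit - 250, summit + 251),
        name=f"p{summit}",
        score=5.0,
        summit=summit,
        enrichment=5.0,
    )
    return standardize_peaks([peak], SIZES)[0]


def track_pair(ip_depth, in_depth, n_ip=1000, l_ip=100, n_in=1000, l_in=100):
    ip = cov.CoverageTrack({"chrT": ip_depth}, n_ip, l_ip, dict(SIZES))
    inp = cov.CoverageTrack({"chrT": in_depth}, n_in, l_in, dict(SIZES))
    return cov.EnrichmentTrack(ip, inp, pseudocount=0.0)


class TestTFEnrichmentAt:
    def test_flat_double_ip(self):
        """IP twice the normalized input everywhere -> fold 2, summit at
        the leftmost core base."""
        enr = track_pair(np.full(50_000, 2.0), np.full(50_000, 1.0))
        r = region_at(10_000)
        (rec,) = conf.tf_enrichment_at([r], enr, "Dl")
        assert rec.enrichment == pytest.approx(2.0)
        assert rec.summit == r.core.start

    def test_summit_at_peak_apex(self):
        depth = np.full(50_000, 1.0)
        depth[10_030] = 50.0
        enr = track_pair(depth, np.full(50_000, 1.0))
        (rec,) = conf.tf_enrichment_at([region_at(10_000)], enr, "Dl")
        assert rec.summit == 10_030

    def test_normalization_arithmetic(self):
        """Window sums 400 (N=1e7, L=200) vs 100 (N=5e6, L=100) -> 1.0."""
        ip_depth = np.zeros(50_000)
        in_depth = np.zeros(50_000)
        r = region_at(10_000)
        ip_depth[r.core.start : r.core.end] = 400.0 / 201
        in_depth[r.core.start : r.core.end] = 100.0 / 201
        # flat outside the window too so summit choice is irrelevant
        ip_depth[:] = 400.0 / 201
        in_depth[:] = 100.0 / 201
        enr = track_pair(ip_depth, in_depth, n_ip=10**7, l_ip=200, n_in=5 * 10**6, l_in=100)
        (rec,) = conf.tf_enrichment_at([r], enr, "Dl")
        assert rec.enrichment == pytest.approx(1.0)


def peak(summit, score, chrom="chrT"):
    return PeakRecord(
        interval=GenomicInterval(chrom, summit - 100, summit + 101),
        name=f"p{summit}",
        score=score,
        summit=summit,
        enrichment=score,
    )


class TestSelectTopPeaks:
    def test_replicate_with_most_peaks_wins(self):
        rep1 = [peak(1000 * (i + 1), 10 + i) for i in range(5)]
        rep2 = [peak(1000 * (i + 1) + 37, 100 + i) for i in range(4)]
        out = conf.select_top_peaks([rep2, rep1], {}, n=3)
        assert all(p.summit % 1000 == 0 for p in out)  # rep1 chosen
        assert [p.score for p in out] == [14, 13, 12]

    def test_tss_peaks_dropped(self):
        peaks = [peak(1000, 50), peak(2000, 40)]
        loc = {("chrT", 1000): "TSS", ("chrT", 2000): "intergenic"}
        out = conf.select_top_peaks([peaks], loc, n=10)
        assert [p.summit for p in out] == [2000]

    def test_shortage_warns(self):
        with pytest.warns(UserWarning, match="requested"):
            out = conf.select_top_peaks([[peak(1000, 1)]], {}, n=400)
        assert len(out) == 1

    def test_score_tie_breaks_leftmost(self):
        out = conf.select_top_peaks([[peak(3000, 5), peak(1000, 5)]], {}, n=1)
        assert out[0].summit == 1000


class TestFisher:
    def test_matches_hypergeometric_tail(self):
        """One-sided Fisher p equals the hypergeometric upper tail sum
        (spot table from the reporter-overlap use case)."""
        k1, n1, k2, n2 = 36, 68, 10, 100
        p = conf.fisher_one_sided_greater(k1, n1, k2, n2)
        # oracle: P(X >= k1), X ~ Hypergeom(N=n1+n2, K=k1+k2, n=n1)
        brute = sum(
            stats.hypergeom.pmf(k, n1 + n2, k1 + k2, n1)
            for k in range(k1, min(n1, k1 + k2) + 1)
        )
        assert p == pytest.approx(brute, rel=1e-10)

    def test_no_association_at_least_half(self):
        assert conf.fisher_one_sided_greater(5, 10, 5, 10) >= 0.5


class TestAnnotationOverlap:
    TILES = [
        (GenomicInterval("chrT", i * 2000, i * 2000 + 2000), i % 2 == 0)
        for i in range(10)
    ]

    def test_fraction_and_p(self):
        group = [GenomicInterval("chrT", 100, 300)]  # tile 0, positive
        control = [GenomicInterval("chrT", 2100, 2300)]  # tile 1, negative
        fg, fc, p = conf.annotation_overlap_test(group, control, self.TILES)
        assert fg == 1.0 and fc == 0.0
        assert 0 < p <= 1

    def test_no_overlap_is_nan(self):
        group = [GenomicInterval("chrT", 30_000, 30_100)]
        with pytest.warns(UserWarning):
            fg, fc, p = conf.annotation_overlap_test(
                group, group, self.TILES[:2]
            )
        assert np.isnan(p)

    def test_proportion_method_agrees_in_direction(self):
        group = [GenomicInterval("chrT", i * 2000 + 10, i * 2000 + 20) for i in range(0, 10, 2)]
        control = [GenomicInterval("chrT", i * 2000 + 10, i * 2000 + 20) for i in range(1, 10, 2)]
        _, _, p_f = conf.annotation_overlap_test(group, control, self.TILES, "fisher")
        _, _, p_z = conf.annotation_overlap_test(group, control, self.TILES, "proportion")
        assert p_f < 0.5 and p_z < 0.5


def make_expr(gene, t, g, n, call):
    return ExpressionRecord(
        gene,
        {"T": t, "G": g, "N": n},
        {PAIR: call},
    )


class TestConfidenceGroups:
    def run_cascade(self, call, folds, expr_call="up_in_T", n_fpkm=1.0, known=()):
        enh = region_at(10_000)
        calls = {enh.id: call}
        tf_enr = {tf: {enh.id: f} for tf, f in folds.items()}
        expr = [make_expr("g1", 10.0, 2.0, n_fpkm, expr_call)]
        groups = conf.assign_confidence_groups(
            [enh],
            calls,
            tf_enr,
            {enh.id: "g1"},
            expr,
            PAIR,
            known_enhancers=list(known),
            third_condition="N",
        )
        return groups[0]

    def test_dl_rule_precedes_twi(self):
        g = self.run_cascade("ME", {"Dl": 3.5, "Twi": 7.0, "Mad": 0, "Zen": 0})
        assert g.group == "Dl_binding"

    def test_twi_group_when_dl_low(self):
        g = self.run_cascade("ME", {"Dl": 2.0, "Twi": 5.0, "Mad": 0, "Zen": 0})
        assert g.group == "Twi"

    def test_dee_cascade(self):
        g = self.run_cascade(
            "DEE", {"Dl": 0, "Twi": 0, "Mad": 2.9, "Zen": 3.0}, expr_call="up_in_G"
        )
        assert g.group == "Zen_binding"

    def test_third_condition_exclusion(self):
        g = self.run_cascade(
            "DEE",
            {"Dl": 0, "Twi": 0, "Mad": 5.0, "Zen": 0},
            expr_call="up_in_G",
            n_fpkm=50.0,
        )
        assert g.group == "unassigned"
        assert g.exclusion_reason == "highest_in_third_condition"

    def test_expression_mismatch_exclusion(self):
        g = self.run_cascade("DEE", {"Dl": 0, "Twi": 0, "Mad": 5.0, "Zen": 0},
                             expr_call="up_in_T")
        assert g.exclusion_reason == "expression_tissue_mismatch"

    def test_known_enhancer_exclusion(self):
        g = self.run_cascade(
            "ME",
            {"Dl": 5.0, "Twi": 0, "Mad": 0, "Zen": 0},
            known=[GenomicInterval("chrT", 9_950, 10_050)],
        )
        assert g.exclusion_reason == "overlaps_known_enhancer"

    def test_missing_tf_record(self):
        g = self.run_cascade("ME", {"Mad": 0, "Zen": 0})
        assert g.exclusion_reason == "missing_tf_record"

    def test_partition_every_call_appears_once(self):
        peaks = [
            PeakRecord(
                interval=GenomicInterval("chrT", s - 250, s + 251),
                name=f"p{s}",
                score=5.0,
                summit=s,
                enrichment=5.0,
            )
            for s in [10_000 + i * 2000 for i in range(6)]
        ]
        enh = standardize_peaks(peaks, SIZES)
        calls = {r.id: ("ME" if i % 2 else "DEE") for i, r in enumerate(enh)}
        tf_enr = {
            tf: {r.id: 4.0 for r in enh} for tf in ("Dl", "Twi", "Mad", "Zen")
        }
        expr = [make_expr("g1", 10, 10, 1, "ns")]
        groups = conf.assign_confidence_groups(
            enh, calls, tf_enr, {r.id: "g1" for r in enh}, expr, PAIR
        )
        assert len(groups) == len(enh)
        assert len({g.enhancer_id for g in groups}) == len(enh)
        assert all(
            g.group != "unassigned" or g.exclusion_reason for g in groups
        )


class TestHeatmapNormalization:
    def test_linear_map(self):
        vals = np.arange(1.0, 102.0)  # p98 = 1 + 0.98*100 = 99
        out = conf.normalize_for_heatmap(vals)
        assert out[49] == pytest.approx((50 - 1) / (99 - 1))
        # halfway between 1 and the 98th percentile maps to 0.5
        assert conf.normalize_for_heatmap(np.r_[vals, 50.0])[-1] == pytest.approx(
            0.5, abs=0.01
        )

    def test_below_one_maps_to_zero(self):
        out = conf.normalize_for_heatmap([0.8, 5.0, 5.0, 5.0])
        assert out[0] == 0.0

    def test_cap_at_one(self):
        vals = [1.0] * 50 + [4.0] * 49 + [100.0]
        out = conf.normalize_for_heatmap(vals)
        assert out[-1] == 1.0

    def test_monotone(self, rng):
        vals = rng.gamma(2, 2, size=200)
        out = conf.normalize_for_heatmap(vals)
        order = np.argsort(vals)
        assert (np.diff(out[order]) >= -1e-12).all()

    def test_degenerate_p98_warns(self):
        with pytest.warns(UserWarning):
            out = conf.normalize_for_heatmap([0.5, 0.6, 0.7])
        assert (out == 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            conf.normalize_for_heatmap([])
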