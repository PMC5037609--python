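"""PWM scanning, DP p-values, background models, and motif enrichment."""
import itertools

import numpy as np
import pytest

from enhancerdiff import motifs as mt
from enhancerdiff.core import ValidationError


def pwm_from_consensus(consensus, motif_id="m", sharp=0.97):
    off = (1 - sharp) / 3
    mat = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        mat[i, mt.BASES.index(b)] = sharp
    return mt.PositionWeightMatrix(motif_id=motif_id, matrix=mat)


class TestPWMValidation:
    def test_rows_must_sum_to_one(self):
        bad = np.full((5, 4), 0.3)
        with pytest.raises(ValidationError):
            mt.PositionWeightMatrix("m", bad)

    def test_min_length(self):
        with pytest.raises(ValidationError):
            mt.PositionWeightMatrix("m", np.full((3, 4), 0.25))


class TestBackground:
    def test_all_a_symmetrized(self):
        bg = mt.build_background(["A" * 2000], order=0)
        p = bg.probs[""]
        assert p[0] == pytest.approx(p[3])  # A == T after symmetrization
        assert p[1] == pytest.approx(p[2])
        assert p[0] > 0.49 and p[1] < 0.01

    def test_uniform_sequence_near_quarter(self, rng):
        seq = "".join(mt.BASES[i] for i in rng.integers(0, 4, size=100_000))
        bg = mt.build_background([seq], order=0)
        np.testing.assert_allclose(bg.probs[""], 0.25, atol=0.02)

    def test_order1_dinucleotide(self):
        bg = mt.build_background(["AC" * 3000], order=1)
        assert bg.probs["A"][mt.BASE_INDEX["C"]] > 0.95

    def test_non_acgtn_rejected(self):
        with pytest.raises(ValidationError, match="X"):
            mt.build_background(["ACGX" * 300], order=0)


class TestScoring:
    def test_consensus_score_arithmetic(self):
        """Two-position PWM at 0.97 vs uniform background scores
        2*log2(0.97/0.25) ~ 3.91 bits at the consensus."""
        # length-4 minimum: use AC consensus twice
        pwm = pwm_from_consensus("ACAC")
        bg = mt.uniform_background()
        hits = mt.scan_pwm(pwm, "ACAC", bg, p_threshold=1.0)
        plus = [h for h in hits if h.strand == "+"][0]
        assert plus.score == pytest.approx(4 * np.log2(0.97 / 0.25), abs=1e-9)

    def test_single_hit_location(self):
        """Scanning GACGT for an ACGT-consensus PWM finds one + hit at
        offset 1."""
        pwm = pwm_from_consensus("ACGT")
        bg = mt.uniform_background()
        hits = mt.scan_pwm(pwm, "GACGT", bg, p_threshold=1e-2)
        strong = [h for h in hits if h.strand == "+" and h.score > 5]
        assert len(strong) == 1 and strong[0].offset == 1

    def test_palindrome_strand_symmetry(self):
        pwm = pwm_from_consensus("ACGT")  # reverse complement of ACGT is ACGT
        bg = mt.uniform_background()
        hits = mt.scan_pwm(pwm, "TTACGTTT", bg, p_threshold=1.0)
        plus = {(h.offset, round(h.score, 9)) for h in hits if h.strand == "+"}
        minus = {(h.offset, round(h.score, 9)) for h in hits if h.strand == "-"}
        assert plus == minus

    def test_n_windows_skipped(self):
        pwm = pwm_from_consensus("ACGT")
        bg = mt.uniform_background()
        hits = mt.scan_pwm(pwm, "ACNGTACGT", bg, p_threshold=1.0)
        # every window touching the N (offsets 0-2) is skipped
        assert hits and {h.offset for h in hits} == {3, 4, 5}

    def test_pwm_longer_than_sequence(self):
        pwm = pwm_from_consensus("ACGTACGT")
        assert mt.scan_pwm(pwm, "ACG", mt.uniform_background()) == []

    def test_brute_force_agreement(self, rng):
        """Hits and scores match a windows-enumerating scorer on a 2-kb
        sequence."""
        seq = "".join(mt.BASES[i] for i in rng.integers(0, 4, size=2000))
        pwm = pwm_from_consensus("ACGTAC", sharp=0.9)
        bg = mt.uniform_background()
        threshold = 1e-3
        hits = mt.scan_pwm(pwm, seq, bg, p_threshold=threshold)

        # independent path: enumerate every window on both strands,
        # score by direct sum of log ratios, decide hits by enumerating
        # all 4^L words for the null
        L = len(pwm)
        lo = np.log2(np.maximum(pwm.matrix, mt.PWM_FLOOR) / 0.25)
        lo_rc = lo[::-1, ::-1]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        words = list(itertools.product(range(4), repeat=L))
        binned = np.rint(lo / mt.SCORE_BIN_BITS).astype(int)

        def word_int_score(word, mat_binned):
            return sum(mat_binned[i, b] for i, b in enumerate(word))

        null = sorted(
            (word_int_score(w, binned), 0.25**L) for w in words
        )
        scores_sorted = np.array([s for s, _ in null])
        probs = np.array([p for _, p in null])
        tail = np.cumsum(probs[::-1])[::-1]

        def pval(int_score):
            i = np.searchsorted(scores_sorted, int_score, side="left")
            return tail[i] if i < len(tail) else 0.0

        expected = []
        for off in range(len(seq) - L + 1):
            w = tuple(mt.BASE_INDEX[c] for c in seq[off : off + L])
            for strand, mat, matb in (("+", lo, binned), ("-", lo_rc, np.rint(lo_rc / mt.SCORE_BIN_BITS).astype(int))):
                s_int = word_int_score(w, matb)
                p = pval(s_int)
                if p <= threshold:
                    s_cont = sum(mat[i, b] for i, b in enumerate(w))
                    expected.append((off, strand, round(s_cont, 6), p))
        got = [(h.offset, h.strand, round(h.score, 6), h.p) for h in hits]
        assert sorted(got) == sorted(expected)
        for (_, _, s1, p1), (_, _, s2, p2) in zip(sorted(got), sorted(expected)):
            assert abs(s1 - s2) < 1e-6
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_dp_pvalues_equal_exhaustive_enumeration(self):
        """DP survival function equals the brute-force sum over all 4^L
        words under a (non-uniform) order-0 background."""
        pwm = pwm_from_consensus("ACGTA", sharp=0.85)
        bg = mt.BackgroundModel(order=0, probs={"": np.array([0.3, 0.2, 0.2, 0.3])})
        pmf, offset = mt.score_distribution(pwm, bg)
        sf = mt.score_pvalues(pmf, offset)
        binned = mt._binned(mt.log_odds_matrix(pwm, bg))
        bgp = bg.probs[""]
        L = len(pwm)
        word_scores = {}
        for w in itertools.product(range(4), repeat=L):
            s = sum(binned[i, b] for i, b in enumerate(w))
            p = np.prod([bgp[b] for b in w])
            word_scores[s] = word_scores.get(s, 0.0) + p
        for s in sorted(word_scores):
            brute = sum(p for t, p in word_scores.items() if t >= s)
            assert sf[s - offset] == pytest.approx(brute, rel=1e-9, abs=1e-12)

    def test_reverse_complement_presence_invariance(self, rng):
        """Reverse-complementing every sequence leaves motif presence
        unchanged (both strands are scanned)."""
        seqs = {
            f"r{i}": "".join(mt.BASES[j] for j in rng.integers(0, 4, size=201))
            for i in range(30)
        }
        comp = str.maketrans("ACGT", "TGCA")
        rc = {k: s.translate(comp)[::-1] for k, s in seqs.items()}
        pwm = pwm_from_consensus("ACGTCA", sharp=0.9)
        bg = mt.uniform_background()
        h1 = mt.scan_regions([pwm], seqs, bg, p_threshold=1e-3)
        h2 = mt.scan_regions([pwm], rc, bg, p_threshold=1e-3)
        p1 = {h.region_id for h in h1[pwm.motif_id]}
        p2 = {h.region_id for h in h2[pwm.motif_id]}
        assert p1 == p2


class TestExpressionFilter:
    def make(self, mid, gene):
        p = pwm_from_consensus("ACGT", motif_id=mid)
        p.tf_gene_id = gene
        return p

    def test_strict_threshold(self):
        pwms = [self.make("kept", "tf1"), self.make("dropped", "tf2")]
        out = mt.filter_motifs_by_expression(
            pwms, {"tf1": 3.5, "tf2": 3.0}, min_fpkm=3.0
        )
        assert [p.motif_id for p in out] == ["kept"]

    def test_exclusion_list(self):
        pwms = [self.make("m1", "tf1")]
        assert (
            mt.filter_motifs_by_expression(pwms, {"tf1": 10.0}, exclusions={"m1"})
            == []
        )

    def test_unmapped_kept_by_default(self):
        p = pwm_from_consensus("ACGT", motif_id="anon")
        assert mt.filter_motifs_by_expression([p], {})[0].motif_id == "anon"


class TestEnrichment:
    def test_hand_computed_proportion_z(self):
        """30/100 vs 10/100: z = 0.2/sqrt(0.2*0.8*0.02) = 3.536,
        p ~ 2.03e-4."""
        p = mt.one_sided_proportion_p(30, 100, 10, 100)
        assert p == pytest.approx(2.03e-4, rel=5e-3)

    def test_equal_proportions(self):
        assert mt.one_sided_proportion_p(10, 100, 10, 100) == pytest.approx(0.5)

    def test_degenerate_motif_skipped(self):
        import pandas as pd

        test = pd.DataFrame({"m": [False] * 100})
        ctrl = pd.DataFrame({"m": [False] * 100})
        assert mt.enrichment_test(test, ctrl) == []

    def test_directions_reported_separately(self):
        import pandas as pd

        test = pd.DataFrame({"m": [True] * 30 + [False] * 70})
        ctrl = pd.DataFrame({"m": [True] * 10 + [False] * 90})
        res = mt.enrichment_test(test, ctrl)
        by_dir = {r.direction: r for r in res}
        assert by_dir["enriched"].p < 0.001
        assert by_dir["depleted"].p > 0.99


def hit(mid, region, offset, strand="+", p=1e-5):
    return mt.MotifHit(mid, region, offset, strand, 10.0, p)


class TestCollapse:
    def res(self, mid, p):
        return mt.MotifEnrichmentResult(mid, "enriched", 1, 1, 0, 1, p, p)

    def test_grouping_with_lowest_p_representative(self):
        # A and B overlap in 2/10 of A's occurrences (20% > 10%)
        hits = {
            "A": [hit("A", f"r{i}", 0) for i in range(10)],
            "B": [hit("B", "r0", 3), hit("B", "r1", 3)]
            + [hit("B", f"q{i}", 0) for i in range(18)],
        }
        groups = mt.collapse_motifs(
            [self.res("A", 1e-5), self.res("B", 1e-3)],
            hits,
            {"A": 8, "B": 8},
        )
        assert len(groups) == 1
        assert groups[0]["representative"] == "A"
        assert groups[0]["members"] == ["A", "B"]

    def test_exact_ten_percent_not_grouped(self):
        hits = {
            "A": [hit("A", f"r{i}", 0) for i in range(10)],
            "B": [hit("B", "r0", 3)] + [hit("B", f"q{i}", 0) for i in range(9)],
        }
        groups = mt.collapse_motifs(
            [self.res("A", 1e-5), self.res("B", 1e-3)], hits, {"A": 8, "B": 8}
        )
        assert len(groups) == 2  # 1/10 overlap is not "more than 10%"

    def test_chained_components(self):
        hits = {
            "A": [hit("A", "r0", 0)],
            "B": [hit("B", "r0", 4), hit("B", "r1", 0)],
            "C": [hit("C", "r1", 4)],
        }
        groups = mt.collapse_motifs(
            [self.res("A", 1e-6), self.res("B", 1e-4), self.res("C", 1e-2)],
            hits,
            {"A": 8, "B": 8, "C": 8},
        )
        assert len(groups) == 1
        assert groups[0]["members"] == ["A", "B", "C"]


class TestTFBindingAtMotif:
    def test_exact_rank_sum(self):
        """All with-motif values larger, 4 vs 4 -> exact two-sided
        p = 2/70."""
        hits = [hit("m", f"w{i}", 0) for i in range(4)]
        enr = {f"w{i}": 10.0 + i for i in range(4)}
        enr.update({f"x{i}": 1.0 + i * 0.1 for i in range(4)})
        ids = list(enr)
        med_w, med_wo, p = mt.tf_binding_at_motif_test(ids, hits, enr)
        assert p == pytest.approx(2 / 70)
        assert med_w > med_wo

    def test_underpowered_group_is_nan(self):
        hits = [hit("m", "w0", 0), hit("m", "w1", 0)]
        enr = {"w0": 5.0, "w1": 6.0, "x0": 1.0, "x1": 2.0, "x2": 3.0}
        _, _, p = mt.tf_binding_at_motif_test(list(enr), hits, enr)
        assert np.isnan(p)


class TestMemeIO:
    def test_round_trip(self, tmp_path):
        pwms = [pwm_from_consensus("ACGTAC", "m1"), pwm_from_consensus("GGGTTT", "m2")]
        pwms[0].tf_name = "twi"
        mt.write_meme(pwms, tmp_path / "m.meme")
        back = mt.read_meme(tmp_path / "m.meme")
        assert [p.motif_id for p in back] == ["m1", "m2"]
        assert back[0].tf_name == "twi"
        np.testing.assert_allclose(back[0].matrix, pwms[0].matrix, atol=1e-6)


class TestPlantedMotifRecovery:
    def test_planted_motif_ranks_first(self, small_dataset, rng):
        """A motif planted in most ME cores but few controls outranks
        decoys in the enrichment test."""
        from enhancerdiff.synthetic import core_sequences

        ds = small_dataset
        truth = ds.truth
        me = truth[truth["class"] == "ME"]
        ctrl = truth[truth["class"] == "nondiff"]
        seqs_me = {
            f"me{i}": s
            for i, s in enumerate(core_sequences(ds, me["summit"].tolist()))
        }
        seqs_ct = {
            f"ct{i}": s
            for i, s in enumerate(core_sequences(ds, ctrl["summit"].tolist()))
        }
        bg = mt.build_background(list(ds.genome.values()), order=0)
        all_seqs = {**seqs_me, **seqs_ct}
        hits = mt.scan_regions(ds.motifs, all_seqs, bg)
        pres = mt.presence_matrix(hits, list(all_seqs))
        res = mt.enrichment_test(
            pres.loc[list(seqs_me)], pres.loc[list(seqs_ct)]
        )
        enriched = sorted(
            [r for r in res if r.direction == "enriched"], key=lambda r: r.p
        )
        assert enriched[0].motif_id == "ME_motif"
        # the small fixture has only 20 ME cores; full-scale power is
        # exercised end-to-end elsewhere
        assert enriched[0].q < 0.05
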