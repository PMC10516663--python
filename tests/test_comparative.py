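"""Pairwise alignment, identity, covariation classes, conservation and
probe concordance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iresscope.comparative import (
    AlignmentError,
    PairwiseAlignment,
    align_pair,
    conservation_stats,
    covariation_report,
    percent_identity,
    probe_concordance,
)
from iresscope.descriptor import StructureAnnotation
from iresscope.seqio import Interval
from iresscope.synthetic import GeneratorParams, evolve_clade, sample_ires

SEQ = st.text(alphabet="ACGU", min_size=1, max_size=40)


def _annotation(pairs, length):
    return StructureAnnotation(
        element_coords={"span": Interval(1, length)},
        pairs=tuple((i, j, "WC") for i, j in pairs),
        pk_groups={}, domains={},
        start_codon=Interval(max(1, length - 2), length),
        start_triplet="GCU",
    )


def _rescore(aln, match=1.0, mismatch=-1.0, gap_open=-5.0, gap_extend=-1.0):
    """Independent scoring of a gapped alignment (affine, first gap
    position costs gap_open, later positions gap_extend)."""
    score = 0.0
    prev_gap_a = prev_gap_b = False
    for x, y in zip(aln.seq_a, aln.seq_b):
        if x == "-":
            score += gap_extend if prev_gap_a else gap_open
            prev_gap_a, prev_gap_b = True, False
        elif y == "-":
            score += gap_extend if prev_gap_b else gap_open
            prev_gap_a, prev_gap_b = False, True
        else:
            score += match if x == y else mismatch
            prev_gap_a = prev_gap_b = False
    return score


class TestAlignPair:
    def test_identical_sequences(self):
        aln = align_pair("ACGUACGUACGUACGUACGU", "ACGUACGUACGUACGUACGU")
        assert "-" not in aln.seq_a + aln.seq_b
        assert aln.score == 20

    def test_single_deletion(self):
        aln = align_pair("ACGU", "AGU")
        gaps = sum(1 for x, y in zip(aln.seq_a, aln.seq_b) if "-" in (x, y))
        assert gaps == 1

    def test_score_matches_independent_rescoring(self, rng):
        for _ in range(25):
            a = "".join("ACGU"[i] for i in rng.integers(0, 4, int(rng.integers(5, 40))))
            b = "".join("ACGU"[i] for i in rng.integers(0, 4, int(rng.integers(5, 40))))
            aln = align_pair(a, b)
            assert aln.score == pytest.approx(_rescore(aln))

    def test_ungapping_reproduces_inputs(self, rng):
        a = "".join("ACGU"[i] for i in rng.integers(0, 4, 30))
        b = "".join("ACGU"[i] for i in rng.integers(0, 4, 25))
        aln = align_pair(a, b)
        assert aln.seq_a.replace("-", "") == a
        assert aln.seq_b.replace("-", "") == b

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            align_pair("", "ACGU")


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity(align_pair("ACGUACGU", "ACGUACGU")) == 100.0

    def test_three_quarters(self):
        aln = PairwiseAlignment("ACGU", "ACGA", 0.0)
        assert percent_identity(aln) == 75.0

    def test_agrees_with_bruteforce_counter(self, rng):
        for _ in range(20):
            a = "".join("ACGU"[i] for i in rng.integers(0, 4, 30))
            b = "".join("ACGU"[i] for i in rng.integers(0, 4, 28))
            aln = align_pair(a, b)
            cols = [(x, y) for x, y in zip(aln.seq_a, aln.seq_b)
                    if x != "-" and y != "-"]
            want = 100.0 * sum(x == y for x, y in cols) / len(cols)
            assert percent_identity(aln) == pytest.approx(want)

    @given(SEQ, SEQ)
    @settings(max_examples=40, derandomize=True)
    def test_symmetric(self, a, b):
        assert percent_identity(align_pair(a, b)) == pytest.approx(
            percent_identity(align_pair(b, a))
        )


class TestCovariation:
    def test_three_identities_covariant(self):
        rows = ["GAAAC", "AAAAU", "UAAAA"]
        report = covariation_report(rows, _annotation([(0, 4)], 5))
        (p,) = report.per_pair
        assert (p.klass, p.support) == ("covariant", 3)

    def test_single_identity_invariant(self):
        rows = ["GAAAC", "GAAAC", "GAAAC"]
        report = covariation_report(rows, _annotation([(0, 4)], 5))
        (p,) = report.per_pair
        assert (p.klass, p.support) == ("invariant", 3)

    def test_broken_pair_inconsistent(self):
        rows = ["GAAAC", "GAAAA", "GAAAA"]
        report = covariation_report(rows, _annotation([(0, 4)], 5))
        (p,) = report.per_pair
        assert p.klass == "inconsistent"
        assert p.support == 1

    def test_strong_threshold_generalizes_22_of_26(self):
        rows = ["GAAAC"] * 26
        report = covariation_report(rows, _annotation([(0, 4)], 5))
        assert report.strong_threshold == 22

    def test_full_compensation_clade_has_no_inconsistent_pairs(self, descriptor_6e):
        rng = np.random.default_rng(8)
        anc = sample_ires(descriptor_6e, rng)
        clade = evolve_clade(anc, GeneratorParams(compensation_prob=1.0,
                                                  substitution_rate=0.08,
                                                  n_taxa=26), rng)
        rows = [m.seq for m in clade.members]  # substitutions only: aligned
        report = covariation_report(rows, anc.annotation)
        assert report.n_members == 26
        assert report.inconsistent_pair_count == 0
        assert all(p.support == 26 for p in report.per_pair)
        assert report.invariant_pair_count + report.covariant_pair_count == len(
            report.per_pair
        )

    def test_no_compensation_lowers_mean_support(self, descriptor_6e):
        rng = np.random.default_rng(9)
        anc = sample_ires(descriptor_6e, rng)
        full = evolve_clade(anc, GeneratorParams(compensation_prob=1.0,
                                                 substitution_rate=0.05,
                                                 n_taxa=26), rng)
        none = evolve_clade(anc, GeneratorParams(compensation_prob=0.0,
                                                 substitution_rate=0.05,
                                                 n_taxa=26), rng)
        rep_full = covariation_report([m.seq for m in full.members], anc.annotation)
        rep_none = covariation_report([m.seq for m in none.members], anc.annotation)
        mean = lambda r: sum(p.support for p in r.per_pair) / len(r.per_pair)
        assert mean(rep_none) < mean(rep_full) == 26.0

    def test_support_counts_match_bruteforce_recount(self, descriptor_6e):
        rng = np.random.default_rng(10)
        anc = sample_ires(descriptor_6e, rng)
        clade = evolve_clade(anc, GeneratorParams(compensation_prob=0.5,
                                                  substitution_rate=0.06,
                                                  n_taxa=12), rng)
        rows = [m.seq for m in clade.members]
        report = covariation_report(rows, anc.annotation)
        wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
        for p in report.per_pair:
            ci, cj = p.columns
            recount = sum(1 for r in rows if (r[ci], r[cj]) in wc)
            assert recount == p.support

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(AlignmentError):
            covariation_report(["GAAAC"], _annotation([(0, 4)], 5))


class TestConservation:
    def test_identical_rows(self):
        stats = conservation_stats(["ACGU", "ACGU", "ACGU"])
        assert stats.fraction_invariant_columns == 1.0

    def test_half_different(self):
        stats = conservation_stats(["AAAA", "AAUU"])
        assert stats.fraction_invariant_columns == 0.5

    def test_matrix_properties(self, rng):
        rows = ["".join("ACGU"[i] for i in rng.integers(0, 4, 30)) for _ in range(4)]
        stats = conservation_stats(rows)
        m = stats.pairwise_identity_matrix
        for i in range(4):
            assert m[i][i] == 100.0
            for j in range(4):
                assert m[i][j] == m[j][i]

    def test_matches_bruteforce_column_scan(self, rng):
        rows = ["".join("ACGU"[i] for i in rng.integers(0, 4, 40)) for _ in range(5)]
        stats = conservation_stats(rows)
        invariant = sum(1 for c in range(40) if len({r[c] for r in rows}) == 1)
        assert stats.fraction_invariant_columns == pytest.approx(invariant / 40)


class TestProbeConcordance:
    def test_all_reactive_in_loops(self):
        ann = _annotation([(0, 9), (1, 8)], 10)
        assert probe_concordance(ann, [4, 5, 6]) == 1.0

    def test_all_reactive_paired(self):
        ann = _annotation([(0, 9), (1, 8)], 10)
        assert probe_concordance(ann, [1, 2, 9, 10]) == 0.0

    def test_noisy_loop_reactivities_near_expected(self, descriptor_6e):
        rng = np.random.default_rng(12)
        s = sample_ires(descriptor_6e, rng)
        paired0 = {p for i, j, _ in s.annotation.pairs for p in (i + 1, j + 1)}
        loops = [p for p in range(1, len(s.record.seq) + 1) if p not in paired0]
        # 10% of reported reactivities mislocated onto paired positions
        n = 200
        noise = rng.random(n) < 0.10
        paired_list = sorted(paired0)
        positions = [
            int(paired_list[rng.integers(0, len(paired_list))]) if flip
            else int(loops[rng.integers(0, len(loops))])
            for flip in noise
        ]
        frac = probe_concordance(s.annotation, positions)
        assert frac == pytest.approx(0.9, abs=0.06)

    def test_empty_positions_rejected(self):
        with pytest.raises(AlignmentError):
            probe_concordance(_annotation([(0, 9)], 10), [])

    def test_out_of_span_rejected(self):
        with pytest.raises(Exception, match="outside"):
            probe_concordance(_annotation([(0, 9)], 10), [99])
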