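"""Descriptor grammar, backtracking matcher (vs. an exhaustive-placement
oracle), border reporting, toeprint prediction and mutation fixtures."""

import itertools

import numpy as np
import pytest

from iresscope.descriptor import (
    DescriptorConfigError,
    HelixElement,
    IresDescriptor,
    LoopElement,
    MatchParams,
    ToeprintRule,
    apply_mutation,
    default_descriptor_6e,
    match_descriptor,
    motif_best_mismatch,
    predict_toeprints,
    report_borders,
    validate_match,
)
from iresscope.energetics import pair_kind
from iresscope.seqio import GenomeRecord, Interval
from iresscope.synthetic import sample_ires


def _record(seq, rid="t"):
    return GenomeRecord(id=rid, seq=seq)


class TestDefaultDescriptor:
    def test_length_bounds(self, descriptor_6e):
        assert descriptor_6e.total_len_range == (142, 154)

    def test_start_codon_set(self, descriptor_6e):
        assert "ACU" in descriptor_6e.allowed_start_codons
        assert "CAA" not in descriptor_6e.allowed_start_codons
        assert descriptor_6e.allowed_start_codons == {
            "GCU", "ACU", "ACC", "UCU", "UCA", "UCG"
        }

    def test_structurally_valid(self, descriptor_6e):
        assert descriptor_6e.crossing_layer_count() <= 3
        names = [t.split(":")[0] for t in descriptor_6e.layout if t != "codon"]
        assert len(set(names)) == len(descriptor_6e.helices) + len(descriptor_6e.loops)

    def test_pseudoknot_grouping(self, descriptor_6e):
        assert descriptor_6e.pk_groups["PKI"] == ("P3.1", "P3.2")
        assert set(descriptor_6e.pk_groups["PKIII"]) == {"P2.1", "P2.2"}

    def test_invalid_configs_rejected(self):
        with pytest.raises(DescriptorConfigError):
            HelixElement("H", 5, 3)
        with pytest.raises(DescriptorConfigError):
            LoopElement("L", 2, 4, motif="ACGUU")


def _oracle_placements(seq, desc):
    """Exhaustive enumeration of all descriptor placements (pair sets).

    Written independently of the backtracking engine: iterate every codon
    position and every combination of element lengths, then verify the
    constraints directly.
    """
    tokens = desc.layout[:-1]
    var_names, ranges = [], []
    for tok in tokens:
        if tok.endswith(":5"):
            h = desc.helices[tok[:-2]]
            var_names.append(tok)
            ranges.append(range(h.min_bp, h.max_bp + 1))
        elif ":" not in tok:
            l = desc.loops[tok]
            var_names.append(tok)
            ranges.append(range(l.min_len, l.max_len + 1))
    out = set()
    for codon_start in range(len(seq) - 2):
        if seq[codon_start : codon_start + 3] not in desc.allowed_start_codons:
            continue
        for combo in itertools.product(*ranges):
            lengths = dict(zip(var_names, combo))
            total = 3 + sum(
                lengths[f"{tok[:-2]}:5"] if tok.endswith(":3") else lengths[tok]
                for tok in tokens
            )
            lo, hi = desc.total_len_range
            if not (lo <= total <= hi):
                continue
            start = codon_start + 3 - total
            if start < 0:
                continue
            # lay out segments left to right
            pos = start
            coords = {}
            for tok in tokens:
                n = lengths[f"{tok[:-2]}:5"] if tok.endswith(":3") else lengths[tok]
                coords[tok] = (pos, pos + n)
                pos += n
            if pos != codon_start:
                continue
            ok = True
            pairs = []
            for h in desc.helices.values():
                a, b = coords[f"{h.name}:5"]
                c, d = coords[f"{h.name}:3"]
                for k in range(b - a):
                    i, j = a + k, d - 1 - k
                    kind = pair_kind(seq[i], seq[j])
                    if kind is None or (kind == "GU" and not h.allow_wobble):
                        ok = False
                        break
                    pairs.append((i, j))
                if not ok:
                    break
                for off, want in h.required_pairs:
                    kk = off if off >= 0 else (b - a) + off
                    i, j = a + kk, d - 1 - kk
                    if pair_kind(seq[i], seq[j]) != want:
                        ok = False
                if not ok:
                    break
            if not ok:
                continue
            for l in desc.loops.values():
                if l.motif:
                    a, b = coords[l.name]
                    if motif_best_mismatch(seq[a:b], l.motif) > l.max_mismatch:
                        ok = False
                        break
            if ok:
                out.add((start, codon_start, frozenset(pairs)))
    return out


class TestMatchDescriptor:
    def test_matches_equal_exhaustive_oracle(self, mini_descriptor, rng):
        hits = 0
        for _ in range(50):
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 60))
            rec = _record(seq)
            got = {
                (m.genome_interval.start0, m.annotation.start_codon.start0,
                 frozenset((i, j) for i, j, _ in m.annotation.pairs))
                for m in match_descriptor(rec, mini_descriptor,
                                          MatchParams(search_window=60))
            }
            want = _oracle_placements(seq, mini_descriptor)
            assert got == want
            hits += len(want)
        assert hits > 0  # the comparison must actually exercise matches

    def test_poly_a_has_no_match(self, descriptor_6e):
        assert match_descriptor(_record("A" * 150), descriptor_6e) == []

    def test_generated_ires_recovered(self, descriptor_6e):
        s = sample_ires(descriptor_6e, np.random.default_rng(11))
        best = match_descriptor(s.record, descriptor_6e, MatchParams(best_only=True))[0]
        assert set(best.annotation.pair_positions()) == {
            (i, j) for i, j, _ in s.annotation.pairs
        }

    def test_every_match_passes_independent_validator(self, descriptor_6e, rng):
        for _ in range(5):
            s = sample_ires(descriptor_6e, rng)
            for m in match_descriptor(s.record, descriptor_6e)[:10]:
                assert validate_match(s.record, m, descriptor_6e) == []

    def test_deterministic_ordering(self, descriptor_6e, rng):
        s = sample_ires(descriptor_6e, rng)
        a = match_descriptor(s.record, descriptor_6e)
        b = match_descriptor(s.record, descriptor_6e)
        assert a == b

    def test_iupac_n_never_pairs(self, mini_descriptor, rng):
        for _ in range(20):
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 50))
            matches = match_descriptor(_record(seq), mini_descriptor,
                                       MatchParams(search_window=50))
            if not matches:
                continue
            m = matches[0]
            i, j, _ = m.annotation.pairs[0]
            broken = seq[:i] + "N" + seq[i + 1 :]
            still = {
                frozenset(x.annotation.pair_positions())
                for x in match_descriptor(_record(broken), mini_descriptor,
                                          MatchParams(search_window=50))
            }
            assert frozenset(m.annotation.pair_positions()) not in still
            return
        raise AssertionError("no mini-descriptor match drawn in 20 sequences")


class TestMutationFixtures:
    """Disruptive substitutions abolish the match; compensatory double
    mutants restore it with the same topology."""

    @pytest.fixture()
    def truth(self, descriptor_6e):
        s = sample_ires(descriptor_6e, np.random.default_rng(5))
        best = match_descriptor(s.record, descriptor_6e, MatchParams(best_only=True))[0]
        return s, best

    def _helix_pair(self, annotation, helix):
        iv5 = annotation.element_coords[f"{helix}:5"]
        iv3 = annotation.element_coords[f"{helix}:3"]
        # middle pair of the helix
        k = (iv5.end0 - iv5.start0) // 2
        return iv5.start0 + k, iv3.end0 - 1 - k

    @staticmethod
    def _disruptive(base, partner):
        return next(x for x in "ACGU" if x != base and pair_kind(x, partner) is None)

    def test_disruption_loses_match(self, descriptor_6e, truth):
        s, best = truth
        i, j = self._helix_pair(s.annotation, "P2.2")
        new = self._disruptive(s.record.seq[i], s.record.seq[j])
        mutant = apply_mutation(s.record, [(i + 1, new)])
        got = match_descriptor(mutant, descriptor_6e, MatchParams(best_only=True))
        assert not got or set(got[0].annotation.pair_positions()) != set(
            best.annotation.pair_positions()
        )

    def test_compensation_restores_match(self, descriptor_6e, truth):
        s, best = truth
        i, j = self._helix_pair(s.annotation, "P2.2")
        a, b = s.record.seq[i], s.record.seq[j]
        # swap the pair identity (e.g. G-C -> C-G), as in compensatory
        # double mutants
        mutant = apply_mutation(s.record, [(i + 1, b), (j + 1, a)])
        got = match_descriptor(mutant, descriptor_6e, MatchParams(best_only=True))
        assert got
        assert set(got[0].annotation.pair_positions()) == set(
            best.annotation.pair_positions()
        )

    def test_empty_edit_list_is_identity(self, truth):
        s, _ = truth
        assert apply_mutation(s.record, []).seq == s.record.seq

    def test_out_of_range_edit_rejected(self, truth):
        s, _ = truth
        with pytest.raises(Exception, match="position"):
            apply_mutation(s.record, [(10_000, "A")])


class TestBorders:
    def test_length_convention(self, descriptor_6e):
        s = sample_ires(descriptor_6e, np.random.default_rng(2))
        m = match_descriptor(s.record, descriptor_6e, MatchParams(best_only=True))[0]
        five, three, length = report_borders(m)
        assert three == m.annotation.start_codon.end
        assert length == three - five + 1
        lo, hi = descriptor_6e.total_len_range
        assert lo <= length <= hi

    def test_generator_truth_lengths_reproduced(self, descriptor_6e):
        for seed in range(1, 11):
            s = sample_ires(descriptor_6e, np.random.default_rng(seed))
            m = match_descriptor(s.record, descriptor_6e, MatchParams(best_only=True))[0]
            _, _, length = report_borders(m)
            assert length == len(s.record.seq)


class TestToeprints:
    def _match_at(self, plus1):
        ann_codon = Interval(plus1, plus1 + 2)
        from iresscope.descriptor import IresMatch, StructureAnnotation

        ann = StructureAnnotation(
            element_coords={}, pairs=(), pk_groups={}, domains={},
            start_codon=ann_codon, start_triplet="GCU",
        )
        return IresMatch(annotation=ann, score=0.0, delta_g=0.0,
                         record_id="t", genome_interval=Interval(max(1, plus1 - 145), plus1 + 2))

    def test_wenling_codon_window(self):
        # GCU at 6906-6908: +16..+18 counting 6906 as +1
        tp = predict_toeprints(self._match_at(6906))
        assert tp["p_site"] == Interval(6921, 6923)

    def test_origin_window(self):
        tp = predict_toeprints(self._match_at(1))
        assert tp["p_site"] == Interval(16, 18)

    def test_alternate_window(self):
        # ACU at 1189-1191: +19..+21
        tp = predict_toeprints(self._match_at(1189))
        assert tp["alternate"] == Interval(1207, 1209)
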