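"""Anchored realignment, reconciliation (projection property), route
selection and the alignment-accuracy statistic."""

import numpy as np
import pytest

from heptatm.fixtures import alignment_from_partner_map
from heptatm.multitemplate import (Anchor, AnchorSet, MultiTemplateAlignment,
                                   alignment_accuracy, anchored_realign,
                                   choose_best_alignment, locate_anchors,
                                   reconcile_alignments)
from heptatm.pairwise import PairwiseAlignment, global_align
from heptatm.profiles import build_profile, one_hot_profile, score_alignment

from conftest import random_sequence
from test_pairwise import enumerate_global_scores


def random_partner_map(rng, la, lb):
    """Strictly increasing partial map from la target positions into lb."""
    k = int(rng.integers(1, min(la, lb) + 1))
    ai = sorted(rng.choice(la, size=k, replace=False))
    bj = sorted(rng.choice(lb, size=k, replace=False))
    partners = [None] * la
    for i, j in zip(ai, bj):
        partners[i] = int(j)
    return partners


class TestAnchoredRealign:
    def test_empty_anchor_set_equals_plain_alignment(self, scheme, rng):
        a = random_sequence(rng, 40)
        b = random_sequence(rng, 38)
        plain = global_align(a, b, scheme)
        anchored = anchored_realign(a, b, AnchorSet([]), scheme=scheme)
        assert (anchored.row_a, anchored.row_b) == (plain.row_a, plain.row_b)
        assert anchored.score == pytest.approx(plain.score)

    def test_all_position_anchors_on_identical_sequences(self, scheme):
        seq = "ACDEFG"
        anchors = AnchorSet([Anchor(f"a{i}", i, i) for i in range(len(seq))])
        aln = anchored_realign(seq, seq, anchors, scheme=scheme)
        assert aln.row_a == seq and aln.row_b == seq

    def test_forced_anchor_matches_constrained_enumeration(self, scheme):
        # the unconstrained optimum aligns the two sequences gap-free;
        # anchoring position 1 to position 3 forces a different alignment
        a, b = "ACDE", "WWACDE"
        anchor = AnchorSet([Anchor("x", 1, 3)])
        got = anchored_realign(a, b, anchor, scheme=scheme)
        pairs = got.aligned_pairs
        assert (1, 3) in pairs
        # constrained brute force: left segments + anchor + right segments
        left = enumerate_global_scores(a[:1], b[:3], scheme)
        right = enumerate_global_scores(a[2:], b[4:], scheme)
        want = left + scheme.score(a[1], b[3]) + right
        assert got.score == pytest.approx(want)
        assert got.score <= global_align(a, b, scheme).score

    def test_out_of_order_anchors_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            AnchorSet([Anchor("a", 5, 5), Anchor("b", 4, 8)])

    def test_out_of_bounds_anchor_rejected(self, scheme):
        anchors = AnchorSet([Anchor("a", 10, 1)])
        with pytest.raises(ValueError, match="out of bounds"):
            anchored_realign("ACD", "ACD", anchors, scheme=scheme)


class TestLocateAnchors:
    def test_conserved_anchor_found(self, scheme, bundle):
        tpl = bundle
        tpl.anchors = {"R3.50": tpl.tm_segments[2][0] + 5}
        target = tpl.sequence.residues
        aln = global_align(target, tpl.sequence, scheme)
        found = locate_anchors(target, tpl, aln)
        assert len(found) == 1
        a = next(iter(found))
        assert a.target_index == a.template_index == tpl.anchors["R3.50"]

    def test_unmatchable_anchor_dropped(self, scheme, bundle):
        tpl = bundle
        j = tpl.tm_segments[0][0] + 3
        tpl.anchors = {"N1.50": j}
        res = tpl.sequence.residues[j]
        # target lacking that residue anywhere near the implied position
        target = tpl.sequence.residues.replace(res, "A" if res != "A" else "G")
        aln = global_align(target, tpl.sequence, scheme)
        assert len(locate_anchors(target, tpl, aln)) == 0


class TestReconcile:
    def test_single_alignment_round_trips(self, scheme, rng):
        a = random_sequence(rng, 30)
        b = random_sequence(rng, 32)
        aln = global_align(a, b, scheme)
        aln.id_b = "t1"
        mta = reconcile_alignments(a, [aln])
        assert mta.n_templates == 1
        proj = mta.project("t1")
        assert (proj.row_a, proj.row_b) == (aln.row_a, aln.row_b)

    def test_gap_free_alignments_stack(self):
        a = "ACDE"
        a1 = PairwiseAlignment(a, "ACDF", 0.0, "t", "t1")
        a2 = PairwiseAlignment(a, "ACDY", 0.0, "t", "t2")
        mta = reconcile_alignments(a, [a1, a2])
        assert mta.target_row == a
        assert mta.template_rows == ["ACDF", "ACDY"]

    def test_projection_property_randomized(self, rng):
        for _ in range(50):
            la = int(rng.integers(4, 25))
            alns = []
            a = random_sequence(rng, la)
            for t in range(int(rng.integers(1, 5))):
                lb = int(rng.integers(3, 25))
                b = random_sequence(rng, lb)
                partners = random_partner_map(rng, la, lb)
                aln = alignment_from_partner_map(a, b, partners, "target",
                                                 f"t{t}")
                alns.append(aln)
            mta = reconcile_alignments(a, alns)
            for aln in alns:
                proj = mta.project(aln.id_b)
                assert (proj.row_a, proj.row_b) == (aln.row_a, aln.row_b)

    def test_coverage_equals_nongap_rows(self, rng):
        a = random_sequence(rng, 15)
        alns = []
        for t in range(3):
            b = random_sequence(rng, 14)
            alns.append(alignment_from_partner_map(
                a, b, random_partner_map(rng, 15, 14), "target", f"t{t}"))
        mta = reconcile_alignments(a, alns)
        partner_maps = [aln.partner_map() for aln in alns]
        for i, cov in enumerate(mta.coverage()):
            assert cov == sum(1 for pm in partner_maps if pm[i] is not None)

    def test_mismatching_target_rejected(self):
        a1 = PairwiseAlignment("ACDE", "ACDE", 0.0, "t", "t1")
        with pytest.raises(ValueError):
            reconcile_alignments("ACDF", [a1])

    def test_bulge_patterns_kept_per_row(self):
        """A one-residue gap inside one template's TM segment must survive
        reconciliation in that row only — neither propagated nor erased."""
        target = "ACDEFGHIKL"
        # template A: insertion between target 4 and 5 (a bulge in A)
        row_a_t = "ACDEF-GHIKL"
        row_a_b = "ACDEFWGHIKL"
        aln_a = PairwiseAlignment(row_a_t, row_a_b, 0.0, "t", "A")
        # template B: gap-free
        aln_b = PairwiseAlignment(target, "ACDEYGHIKLM"[:10], 0.0, "t", "B")
        mta = reconcile_alignments(target, [aln_a, aln_b])
        pa = mta.project("A")
        pb = mta.project("B")
        assert (pa.row_a, pa.row_b) == (row_a_t, row_a_b)
        assert (pb.row_a, pb.row_b) == (aln_b.row_a, aln_b.row_b)


class TestChooseBest:
    def test_single_candidate_returned(self, scheme):
        p = one_hot_profile("ACDE")
        aln = PairwiseAlignment("ACDE", "ACDE", 0.0)
        route, got = choose_best_alignment([("psa", aln)], p, p, scheme)
        assert route == "psa" and got is aln

    def test_duplicates_resolve_to_earlier_route(self, scheme):
        p = one_hot_profile("ACDE")
        aln = PairwiseAlignment("ACDE", "ACDE", 0.0)
        route, _ = choose_best_alignment(
            [("profile", aln), ("msa", aln), ("psa", aln)], p, p, scheme)
        assert route == "psa"

    def test_maximum_chosen_and_verified_by_rescoring(self, scheme, rng):
        a = random_sequence(rng, 20)
        b = random_sequence(rng, 20)
        pa = build_profile(a, [random_sequence(rng, 20)], scheme, 0.1)
        pb = build_profile(b, [random_sequence(rng, 20)], scheme, 0.1)
        candidates = [
            ("psa", global_align(a, b, scheme)),
            ("msa", alignment_from_partner_map(
                a, b, [i if i % 2 == 0 else None for i in range(20)])),
            ("profile", alignment_from_partner_map(
                a, b, [i if i < 10 else None for i in range(20)])),
        ]
        route, best = choose_best_alignment(candidates, pa, pb, scheme)
        best_score = score_alignment(best, pa, pb, scheme)
        for _, cand in candidates:
            assert best_score >= score_alignment(cand, pa, pb, scheme) - 1e-9

    def test_empty_candidates_rejected(self, scheme):
        p = one_hot_profile("ACDE")
        with pytest.raises(ValueError):
            choose_best_alignment([], p, p, scheme)


class TestAlignmentAccuracy:
    def test_identical_alignments_score_one(self, scheme, rng):
        a = random_sequence(rng, 20)
        b = random_sequence(rng, 18)
        aln = global_align(a, b, scheme)
        assert alignment_accuracy(aln, aln) == 1.0

    def test_completely_different_pairings_score_zero(self):
        a, b = "ACDE", "ACDE"
        test = alignment_from_partner_map(a, b, [0, 1, 2, 3])
        ref = alignment_from_partner_map(a, b, [1, 2, 3, None])
        assert alignment_accuracy(test, ref) == 0.0

    def test_three_of_four_positions(self):
        a, b = "ACDE", "ACDEF"
        test = alignment_from_partner_map(a, b, [0, 1, 2, 3])
        ref = alignment_from_partner_map(a, b, [0, 1, 2, 4])
        assert alignment_accuracy(test, ref) == 0.75

    def test_gap_pairing_counts_as_partner(self):
        a, b = "ACDE", "ACD"
        test = alignment_from_partner_map(a, b, [0, 1, 2, None])
        ref = alignment_from_partner_map(a, b, [0, 1, None, 2])
        # positions 0 and 1 agree; 2 and 3 disagree (residue vs gap)
        assert alignment_accuracy(test, ref) == 0.5

    def test_one_more_agreement_adds_exactly_one_over_l(self, rng):
        a = random_sequence(rng, 10)
        b = random_sequence(rng, 10)
        ref = alignment_from_partner_map(a, b, list(range(10)))
        worse = alignment_from_partner_map(
            a, b, [None, None] + list(range(2, 10)))
        better = alignment_from_partner_map(
            a, b, [0, None] + list(range(2, 10)))
        delta = alignment_accuracy(better, ref) - alignment_accuracy(worse, ref)
        assert delta == pytest.approx(1.0 / 10)

    def test_sequence_mismatch_rejected(self):
        t1 = PairwiseAlignment("ACDE", "ACDE", 0.0)
        t2 = PairwiseAlignment("ACDF", "ACDF", 0.0)
        with pytest.raises(ValueError):
            alignment_accuracy(t1, t2)
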