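"""Superposition (vs. a quaternion oracle) and multi-template coordinate
averaging, including the noise-averaging 1/sqrt(k) recovery experiment."""

import numpy as np
import pytest

from heptatm.fixtures import BundleSpec, make_bundle, perturb_structure
from heptatm.io_formats import ResidueEntry, SequenceRecord, TemplateRecord
from heptatm.multitemplate import reconcile_alignments
from heptatm.pairwise import PairwiseAlignment
from heptatm.structure import (average_model, kabsch_superpose,
                               map_template_coords, transfer_gap_structure)

from conftest import random_chain_template


def quaternion_superpose_rmsd(A, B):
    """Independent oracle: optimal superposition RMSD via Horn's
    quaternion eigenvalue method."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    a = A - A.mean(axis=0)
    b = B - B.mean(axis=0)
    M = b.T @ a
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(N)[-1]
    e2 = float((a ** 2).sum() + (b ** 2).sum())
    msd = max(e2 - 2.0 * lam, 0.0) / len(A)
    return np.sqrt(msd)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])


class TestKabsch:
    def test_self_superposition_is_identity(self, rng):
        X = rng.normal(size=(30, 3)) * 10
        sp = kabsch_superpose(X, X)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sp.rotation, np.eye(3), atol=1e-8)

    def test_recovers_planted_rigid_transform(self, rng):
        X = rng.normal(size=(50, 3)) * 15
        R = random_rotation(rng)
        t = rng.normal(size=3) * 5
        sp = kabsch_superpose(X, X @ R.T + t)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-8)
        moved = sp.apply(X @ R.T + t)
        assert np.allclose(moved, X, atol=1e-8)

    def test_matches_quaternion_oracle_on_noisy_pairs(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 60))
            A = rng.normal(size=(n, 3)) * 12
            B = A + rng.normal(size=(n, 3)) * rng.uniform(0.1, 3.0)
            R = random_rotation(rng)
            B = B @ R.T + rng.normal(size=3)
            sp = kabsch_superpose(A, B)
            assert sp.rmsd == pytest.approx(quaternion_superpose_rmsd(A, B),
                                            abs=1e-6)

    def test_rotation_is_proper(self, rng):
        # a mirrored cloud must not be matched with an improper rotation
        X = rng.normal(size=(20, 3)) * 8
        Y = X.copy()
        Y[:, 0] *= -1
        sp = kabsch_superpose(X, Y)
        assert np.linalg.det(sp.rotation) == pytest.approx(1.0)
        assert sp.rmsd > 0.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _identity_mta(target_seq, template_ids):
    alns = [PairwiseAlignment(target_seq, target_seq, 0.0, "target", tid)
            for tid in template_ids]
    return reconcile_alignments(target_seq, alns)


class TestMapTemplateCoords:
    def test_identity_alignment_single_template(self, rng):
        tpl = random_chain_template(rng, 20, "t1")
        mta = _identity_mta(tpl.sequence.residues, ["t1"])
        cands = map_template_coords(mta, [tpl])
        assert all(len(c) == 1 for c in cands)
        for i, c in enumerate(cands):
            assert np.array_equal(c[0][1].ca, tpl.residues[i].ca)

    def test_gap_only_residue_has_empty_candidates(self, rng):
        tpl = random_chain_template(rng, 5, "t1")
        target = tpl.sequence.residues + "W"
        aln = PairwiseAlignment(target, tpl.sequence.residues + "-", 0.0,
                                "target", "t1")
        mta = reconcile_alignments(target, [aln])
        cands = map_template_coords(mta, [tpl])
        assert len(cands[-1]) == 0

    def test_multiplicities_match_nongap_counts(self, rng):
        t1 = random_chain_template(rng, 12, "t1")
        t2 = random_chain_template(rng, 12, "t2")
        target = t1.sequence.residues
        a1 = PairwiseAlignment(target, t1.sequence.residues, 0.0, "t", "t1")
        partners = [i if i % 3 else None for i in range(12)]
        from heptatm.fixtures import alignment_from_partner_map
        a2 = alignment_from_partner_map(target, t2.sequence.residues, partners,
                                        "t", "t2")
        mta = reconcile_alignments(target, [a1, a2])
        cands = map_template_coords(mta, [t1, t2])
        for i, c in enumerate(cands):
            want = 1 + (1 if partners[i] is not None else 0)
            assert len(c) == want

    def test_unknown_template_id_rejected(self, rng):
        tpl = random_chain_template(rng, 5, "t1")
        mta = _identity_mta(tpl.sequence.residues, ["zzz"])
        with pytest.raises(ValueError):
            map_template_coords(mta, [tpl])


class TestAverageModel:
    def test_single_template_reproduces_coordinates(self, rng):
        tpl = random_chain_template(rng, 25, "t1")
        mta = _identity_mta(tpl.sequence.residues, ["t1"])
        model = average_model(mta, [tpl], weights=[1.0])
        assert np.allclose(model.ca_coords(), tpl.ca_coords(), atol=1e-12)

    def test_symmetric_perturbations_cancel(self, rng):
        truth = random_chain_template(rng, 30, "truth")
        delta = np.zeros((30, 3))
        delta[:, 0] = 0.8
        plus = random_chain_template(rng, 30, "plus")
        minus = random_chain_template(rng, 30, "minus")
        for rec, d in ((plus, delta), (minus, -delta)):
            rec.sequence = SequenceRecord(rec.id, truth.sequence.residues)
            for i, r in enumerate(rec.residues):
                r.name = truth.sequence.residues[i]
                r.atoms = {"CA": truth.residues[i].ca + d[i]}
        mta = _identity_mta(truth.sequence.residues, ["plus", "minus"])
        model = average_model(mta, [plus, minus], weights=[0.5, 0.5])
        got = model.ca_coords()
        want = truth.ca_coords()
        # superposition of 'minus' onto 'plus' may shift the frame; compare
        # after a final fit onto the truth
        sp = kabsch_superpose(want, got)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_noise_averaging_improves_rmsd_at_one_over_sqrt_k(self, rng):
        """k noisy copies of the truth average to a model ~sqrt(k) closer."""
        n, sigma, n_seeds = 200, 1.0, 20
        for k in (2, 3):
            model_rmsds, template_rmsds = [], []
            for s in range(n_seeds):
                local = np.random.default_rng(1000 * k + s)
                truth = random_chain_template(local, n, "truth")
                templates = []
                for t in range(k):
                    tpl = random_chain_template(local, n, f"t{t}")
                    tpl.sequence = SequenceRecord(
                        tpl.id, truth.sequence.residues)
                    for i, r in enumerate(tpl.residues):
                        r.name = truth.sequence.residues[i]
                        r.atoms = {"CA": truth.residues[i].ca
                                   + local.normal(0, sigma, 3)}
                    templates.append(tpl)
                mta = _identity_mta(truth.sequence.residues,
                                    [t.id for t in templates])
                model = average_model(mta, templates, weights=[1.0] * k)
                truth_ca = truth.ca_coords()
                model_rmsds.append(
                    kabsch_superpose(truth_ca, model.ca_coords()).rmsd)
                template_rmsds.append(np.mean(
                    [kabsch_superpose(truth_ca, t.ca_coords()).rmsd
                     for t in templates]))
            mean_model = np.mean(model_rmsds)
            mean_tpl = np.mean(template_rmsds)
            assert mean_model < mean_tpl
            assert mean_model / mean_tpl == pytest.approx(1 / np.sqrt(k),
                                                          rel=0.15)

    def test_invariant_to_rigid_pretransform_of_a_template(self, rng):
        truth = random_chain_template(rng, 40, "truth")
        t1 = perturb_structure_chain(truth, rng, 0.5, "t1")
        t2 = perturb_structure_chain(truth, rng, 0.5, "t2")
        mta = _identity_mta(truth.sequence.residues, ["t1", "t2"])
        base = average_model(mta, [t1, t2], weights=[0.5, 0.5]).ca_coords()
        R = random_rotation(rng)
        t = rng.normal(size=3) * 30
        for r in t2.residues:
            r.atoms = {"CA": R @ r.ca + t}
        moved = average_model(mta, [t1, t2], weights=[0.5, 0.5]).ca_coords()
        assert np.allclose(base, moved, atol=1e-6)

    def test_zero_templates_rejected(self, rng):
        tpl = random_chain_template(rng, 5, "t1")
        mta = _identity_mta(tpl.sequence.residues, ["t1"])
        with pytest.raises(ValueError):
            average_model(mta, [], weights=[])

    def test_uncovered_residues_flagged_without_coordinates(self, rng):
        tpl = random_chain_template(rng, 6, "t1")
        target = tpl.sequence.residues + "WW"
        from heptatm.fixtures import alignment_from_partner_map
        aln = alignment_from_partner_map(target, tpl.sequence.residues,
                                         list(range(6)) + [None, None],
                                         "t", "t1")
        mta = reconcile_alignments(target, [aln])
        model = average_model(mta, [tpl], weights=[1.0])
        assert model.coverage[-2:] == [0, 0]
        assert model.residues[-1].ca is None
        assert model.region_labels[-2:] == ["C-term", "C-term"]


def perturb_structure_chain(truth, rng, sigma, new_id):
    tpl = random_chain_template(rng, len(truth.residues), new_id)
    tpl.sequence = SequenceRecord(new_id, truth.sequence.residues)
    for i, r in enumerate(tpl.residues):
        r.name = truth.sequence.residues[i]
        r.atoms = {"CA": truth.residues[i].ca + rng.normal(0, sigma, 3)}
    return tpl


class TestTransferGapStructure:
    def test_gap_free_mta_reports_nothing(self, rng):
        tpl = random_chain_template(rng, 10, "t1")
        mta = _identity_mta(tpl.sequence.residues, ["t1"])
        assert transfer_gap_structure(mta, [tpl], weights=[1.0]) == []

    def test_tm4_insertion_named_per_template(self):
        """Template A carries a one-residue TM4 bulge the target lacks;
        template B does not — the report must name TM4 and attribute the
        insertion to A only."""
        bulged = make_bundle(BundleSpec(seed=5, bulges=[(3, 10, 1)]))
        plain = make_bundle(BundleSpec(seed=5))
        bulged.id = "A"
        bulged.sequence.id = "A"
        plain.id = "B"
        plain.sequence.id = "B"
        target = plain.sequence.residues
        s4 = plain.tm_segments[3]
        bulge_pos = s4[0] + 10
        partners_a = list(range(bulge_pos)) + \
            [j + 1 for j in range(bulge_pos, len(target))]
        from heptatm.fixtures import alignment_from_partner_map
        aln_a = alignment_from_partner_map(target, bulged.sequence.residues,
                                           partners_a, "t", "A")
        aln_b = PairwiseAlignment(target, plain.sequence.residues, 0.0,
                                  "t", "B")
        mta = reconcile_alignments(target, [aln_a, aln_b])
        sites = transfer_gap_structure(mta, [bulged, plain],
                                       weights=[0.6, 0.4])
        assert any(s.tm == "TM4" and s.kind == "insertion"
                   and s.pattern["A"] == "insertion"
                   and s.pattern["B"] == "none" for s in sites)

    def test_bulged_template_dominates_inherited_geometry(self):
        """When the target aligns gap-free to the bulged template and with a
        gap to the unbulged one, the built model keeps a continuous helix
        through the bulge site (the extra residue is covered and placed)."""
        bulged = make_bundle(BundleSpec(seed=5, bulges=[(3, 10, 1)]))
        plain = make_bundle(BundleSpec(seed=5))
        bulged.id = "A"
        bulged.sequence.id = "A"
        plain.id = "B"
        plain.sequence.id = "B"
        target = bulged.sequence.residues      # target has the bulge residue
        s4 = bulged.tm_segments[3]
        bulge_pos = s4[0] + 10
        aln_a = PairwiseAlignment(target, bulged.sequence.residues, 0.0,
                                  "t", "A")
        partners_b = list(range(bulge_pos)) + [None] + \
            [j for j in range(bulge_pos, len(plain.sequence.residues))]
        from heptatm.fixtures import alignment_from_partner_map
        aln_b = alignment_from_partner_map(target, plain.sequence.residues,
                                           partners_b, "t", "B")
        mta = reconcile_alignments(target, [aln_a, aln_b])
        model = average_model(mta, [bulged, plain], weights=[0.7, 0.3])
        sites = transfer_gap_structure(mta, [bulged, plain],
                                       weights=[0.7, 0.3])
        assert any(s.tm == "TM4" and s.pattern["B"] == "deletion"
                   and s.inherited_from == "A" for s in sites)
        assert model.coverage[bulge_pos] >= 1
        cas = model.ca_coords()[s4[0]:s4[1] + 1]
        steps = np.linalg.norm(np.diff(cas, axis=0), axis=1)
        assert np.all(steps < 5.0)   # helix continuity through the bulge
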