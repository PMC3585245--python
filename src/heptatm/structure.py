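"""Rigid-body superposition and multi-template coordinate averaging.

The model builder takes a reconciled multi-template alignment plus the
template coordinates, superposes all templates onto the first over the
shared TM core, and sets each target residue's backbone coordinates to the
weighted mean of the template coordinates aligned to it (weights default
to each template's percent identity with the target, normalized). This is
a deliberate desk-scale surrogate for restraint-based model building: it
produces TM-core backbones whose quality directly reflects the averaging,
not refined all-atom models. Residues no template covers are flagged and
left without coordinates, never invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import (GAP, BACKBONE_ATOMS, MembraneSlab, ResidueEntry,
                         StructureModel, TemplateRecord)
from .multitemplate import MultiTemplateAlignment
from .pairwise import global_align, percent_identity
from .scoring import ScoringScheme, blosum62


@dataclass(frozen=True)
class Superposition:
    """A proper rigid transform mapping one coordinate set onto another."""

    rotation: np.ndarray      # (3, 3), orthonormal, det +1
    translation: np.ndarray   # (3,)
    rmsd: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be 3x3 orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares optimal proper rotation + translation of b onto a.

    Standard Kabsch algorithm via SVD of the covariance matrix, with the
    determinant sign correction that excludes improper rotations.
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))
    return Superposition(R, t, rmsd)


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def map_template_coords(mta: MultiTemplateAlignment,
                        templates: Sequence[TemplateRecord],
                        ) -> list[list[tuple[str, ResidueEntry]]]:
    """Per target residue: the template residues aligned to it.

    Residues aligned only to gaps get an empty candidate list (coverage 0).
    """
    by_id = {t.id: t for t in templates}
    missing = [tid for tid in mta.template_ids if tid not in by_id]
    if missing:
        raise ValueError(f"templates missing from records: {missing}")
    out: list[list[tuple[str, ResidueEntry]]] = []
    for entries in mta.column_map():
        out.append([(tid, by_id[tid].residues[j]) for tid, j in entries])
    return out


def _tm_core_columns(mta: MultiTemplateAlignment,
                     templates: dict[str, TemplateRecord]) -> list[list[int]]:
    """Template residue indices (per template) of MTA columns where every
    template is non-gap and inside an annotated TM segment."""
    def in_tm(rec: TemplateRecord, j: int) -> bool:
        return any(s <= j < e for s, e in rec.tm_segments)

    counters = [0] * mta.n_templates
    core: list[list[int]] = [[] for _ in mta.template_ids]
    for k in range(len(mta)):
        cols = [mta.template_rows[t][k] for t in range(mta.n_templates)]
        idx = [counters[t] if cols[t] != GAP else None
               for t in range(mta.n_templates)]
        if all(c != GAP for c in cols) and all(
                in_tm(templates[mta.template_ids[t]], idx[t])
                for t in range(mta.n_templates)):
            for t in range(mta.n_templates):
                core[t].append(idx[t])
        for t in range(mta.n_templates):
            if cols[t] != GAP:
                counters[t] += 1
    return core


def template_weights(mta: MultiTemplateAlignment,
                     templates: Sequence[TemplateRecord],
                     scheme: ScoringScheme | None = None) -> np.ndarray:
    """Default averaging weights: normalized target-template percent identity."""
    scheme = scheme or blosum62()
    target = mta.target_sequence
    w = []
    for tid in mta.template_ids:
        rec = next(t for t in templates if t.id == tid)
        aln = global_align(target, rec.sequence.residues, scheme)
        w.append(percent_identity(aln))
    w = np.asarray(w, float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    return w / w.sum()


def average_model(mta: MultiTemplateAlignment,
                  templates: Sequence[TemplateRecord],
                  weights: Sequence[float] | None = None,
                  scheme: ScoringScheme | None = None) -> StructureModel:
    """Build the target backbone as the weighted average of the templates.

    Templates 2..N are first superposed onto template 1 over the CA atoms
    of the mutually aligned TM-core columns; each covered target residue's
    coordinates are then the weighted mean of its aligned template
    coordinates. Region labels transfer from the highest-weight covering
    template's TM/H8 annotation.
    """
    if not templates:
        raise ValueError("at least one template is required")
    by_id = {t.id: t for t in templates}
    if weights is None:
        w = template_weights(mta, templates, scheme)
    else:
        w = np.asarray(weights, float)
        if w.shape != (mta.n_templates,):
            raise ValueError("one weight per template required")
        w = w / w.sum()

    transforms: dict[str, Superposition | None] = {mta.template_ids[0]: None}
    if mta.n_templates > 1:
        core = _tm_core_columns(mta, by_id)
        ref_rec = by_id[mta.template_ids[0]]
        ref_coords = np.array([ref_rec.residues[j].ca for j in core[0]])
        for t in range(1, mta.n_templates):
            tid = mta.template_ids[t]
            rec = by_id[tid]
            mob = np.array([rec.residues[j].ca for j in core[t]])
            if len(mob) < 3:
                raise ValueError(
                    f"TM core shared by all templates has {len(mob)} residues; "
                    "cannot superpose")
            transforms[tid] = kabsch_superpose(ref_coords, mob)

    candidates = mta.column_map()
    target_seq = mta.target_sequence
    order = np.argsort(-w, kind="stable")  # highest-weight template first
    rank = {mta.template_ids[int(t)]: r for r, t in enumerate(order)}
    weight_of = {tid: float(w[t]) for t, tid in enumerate(mta.template_ids)}

    residues: list[ResidueEntry] = []
    labels: list[str] = []
    coverage: list[int] = []
    tpl_labels = {t.id: t.region_labels() for t in templates}
    for i, cands in enumerate(candidates):
        atoms: dict[str, np.ndarray] = {}
        if cands:
            for atom_name in BACKBONE_ATOMS:
                num = np.zeros(3)
                den = 0.0
                for tid, j in cands:
                    coord = by_id[tid].residues[j].atoms.get(atom_name)
                    if coord is None:
                        continue
                    sp = transforms[tid]
                    moved = coord if sp is None else sp.apply(coord)
                    num += weight_of[tid] * np.asarray(moved, float)
                    den += weight_of[tid]
                if den > 0:
                    atoms[atom_name] = num / den
        residues.append(ResidueEntry(i + 1, target_seq[i], atoms))
        coverage.append(len(cands))
        if cands:
            best_tid, best_j = min(cands, key=lambda c: rank[c[0]])
            labels.append(tpl_labels[best_tid][best_j])
        else:
            labels.append("loop")
    # uncovered flanks are termini, not loops
    covered = [i for i, c in enumerate(coverage) if c > 0]
    if covered:
        for i in range(covered[0]):
            labels[i] = "N-term"
        for i in range(covered[-1] + 1, len(labels)):
            labels[i] = "C-term"
    frame = by_id[mta.template_ids[0]].membrane_frame
    return StructureModel(residues, labels, coverage, frame,
                          id=f"{mta.target_id}_model")


@dataclass
class BulgeSite:
    """An insertion/deletion pattern inside a TM segment."""

    tm: str                              # e.g. "TM4"
    kind: str                            # "insertion" or "deletion"
    target_position: int                 # 0-based target residue before/at site
    pattern: dict[str, str]              # template id -> "insertion"/"deletion"/"none"
    inherited_from: str                  # covering highest-weight template
    inherited: str                       # pattern the model inherits


def transfer_gap_structure(mta: MultiTemplateAlignment,
                           templates: Sequence[TemplateRecord],
                           weights: Sequence[float] | None = None,
                           scheme: ScoringScheme | None = None,
                           ) -> list[BulgeSite]:
    """Report, per TM segment, which templates contribute an insertion or
    deletion (helix bulge present/absent) and which pattern the built model
    inherits — that of the highest-weight template covering the site."""
    by_id = {t.id: t for t in templates}
    if weights is None:
        w = template_weights(mta, templates, scheme)
    else:
        w = np.asarray(weights, float)
    tpl_labels = {t.id: t.region_labels() for t in templates}

    def tm_label(tid: str, j: int) -> str | None:
        lab = tpl_labels[tid][j]
        return lab if lab.startswith("TM") else None

    sites: list[BulgeSite] = []
    counters = [0] * mta.n_templates
    ti = 0
    for k in range(len(mta)):
        ct = mta.target_row[k]
        col_idx = [counters[t] if mta.template_rows[t][k] != GAP else None
                   for t in range(mta.n_templates)]
        if ct == GAP:
            # a template insertion; inside a TM helix it is a bulge
            for t, j in enumerate(col_idx):
                if j is None:
                    continue
                tid = mta.template_ids[t]
                tm = tm_label(tid, j)
                if tm is None:
                    continue
                pattern = {u: "none" for u in mta.template_ids}
                pattern[tid] = "insertion"
                covering = [(w[u], mta.template_ids[u])
                            for u, ju in enumerate(col_idx) if ju is not None]
                inh_tid = max(covering)[1]
                sites.append(BulgeSite(tm, "insertion", ti, pattern, inh_tid,
                                       pattern[inh_tid]))
        else:
            # a template gap at an aligned target residue inside its helix
            gap_templates = []
            tms = set()
            for t in range(mta.n_templates):
                tid = mta.template_ids[t]
                if col_idx[t] is None:
                    # locate the helix from the flanking residues
                    j_prev = counters[t] - 1
                    if 0 <= j_prev and counters[t] < len(by_id[tid].residues):
                        lab1 = tm_label(tid, j_prev)
                        lab2 = tm_label(tid, counters[t])
                        if lab1 is not None and lab1 == lab2:
                            gap_templates.append(tid)
                            tms.add(lab1)
                else:
                    tm = tm_label(tid, col_idx[t])
                    if tm is not None:
                        tms.add(tm)
            if gap_templates and tms:
                pattern = {u: ("deletion" if u in gap_templates else "none")
                           for u in mta.template_ids}
                covering = [(w[u], mta.template_ids[u])
                            for u, ju in enumerate(col_idx) if ju is not None]
                if covering:
                    inh_tid = max(covering)[1]
                    sites.append(BulgeSite(sorted(tms)[0], "deletion", ti,
                                           pattern, inh_tid, pattern[inh_tid]))
        for t in range(mta.n_templates):
            if col_idx[t] is not None:
                counters[t] += 1
        if ct != GAP:
            ti += 1
    return sites
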