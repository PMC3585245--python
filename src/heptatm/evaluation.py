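"""Model assessment: region-wise CA RMSD, binding-site heavy-atom RMSD
with the 5 Å-sphere site definition, and the TM-score.

The binding site is the set of residues having at least one heavy atom
within 5 Å of any ligand heavy atom in the reference structure. The
binding-site RMSD is measured (not fitted) in the frame of the full-CA
superposition. The TM-score is computed natively over a given residue
correspondence:

    TM = max over superpositions of (1/L) * sum_i 1 / (1 + (d_i/d0)^2),
    d0 = 1.24 * (L - 15)^(1/3) - 1.8

with the published heuristic search: seed fragments of lengths L, L/2 and
L/4 slid along the chain, each refined by iterating the superposition on
the residues currently within d0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import StructureModel, TemplateRecord
from .structure import kabsch_superpose

BINDING_SITE_RADIUS = 5.0  # Å


@dataclass
class EvaluationReport:
    """Model-vs-reference metrics."""

    ca_rmsd_full: float
    ca_rmsd_tm: float | None
    binding_site_rmsd: float | None
    tm_score: float | None
    n_residues_compared: int
    binding_site_residues: list[int]

    def to_dict(self) -> dict:
        return {
            "ca_rmsd_full": self.ca_rmsd_full,
            "ca_rmsd_tm": self.ca_rmsd_tm,
            "binding_site_rmsd": self.binding_site_rmsd,
            "tm_score": self.tm_score,
            "n_residues_compared": self.n_residues_compared,
            "binding_site_residues": [i + 1 for i in self.binding_site_residues],
        }


def _residue_heavy_coords(residues) -> list[np.ndarray]:
    return [r.heavy_coords() for r in residues]


def binding_site_residues(reference, radius: float = BINDING_SITE_RADIUS,
                          ) -> list[int]:
    """Residues with >= 1 heavy atom within *radius* of >= 1 ligand heavy
    atom of the reference structure. 0-based indices, ascending."""
    ligand = getattr(reference, "ligand_atoms", None)
    if not ligand:
        raise ValueError("reference has no ligand atoms")
    lig = np.asarray(ligand, float)
    out = []
    for i, res in enumerate(reference.residues):
        coords = res.heavy_coords()
        if coords.size and cdist(coords, lig).min() <= radius:
            out.append(i)
    return out


def _ca_matrix(obj, indices) -> np.ndarray:
    return np.array([obj.residues[i].ca for i in indices], dtype=float)


def _tm_indices(obj) -> list[int]:
    if isinstance(obj, TemplateRecord):
        labels = obj.region_labels()
    else:
        labels = obj.region_labels
    return [i for i, lab in enumerate(labels) if lab.startswith("TM")]


def rmsd_report(model, reference, correspondence: Sequence[tuple[int, int]] | None = None,
                compute_tm_score: bool = True) -> EvaluationReport:
    """Evaluate a model against a reference structure.

    ``correspondence`` maps model residue indices to reference residue
    indices (identity over residues with CA on both sides by default).
    Full-chain CA RMSD is computed after a Kabsch fit on all corresponded
    CA; the TM RMSD after a fit on TM-labeled residues only; the
    binding-site heavy-atom RMSD is measured in the full-CA frame.
    """
    if correspondence is None:
        n = min(len(model.residues), len(reference.residues))
        correspondence = [(i, i) for i in range(n)
                          if model.residues[i].ca is not None
                          and reference.residues[i].ca is not None]
    correspondence = list(correspondence)
    if not correspondence:
        raise ValueError("empty model-reference correspondence")
    mi = [i for i, _ in correspondence]
    ri = [j for _, j in correspondence]
    mca = _ca_matrix(model, mi)
    rca = _ca_matrix(reference, ri)
    fit = kabsch_superpose(rca, mca)
    ca_rmsd_full = fit.rmsd

    # TM-region RMSD: fit and measure on TM-labeled corresponded residues
    tm_model = set(_tm_indices(model))
    tm_pairs = [(i, j) for i, j in correspondence if i in tm_model]
    ca_rmsd_tm = None
    if len(tm_pairs) >= 3:
        tfit = kabsch_superpose(_ca_matrix(reference, [j for _, j in tm_pairs]),
                                _ca_matrix(model, [i for i, _ in tm_pairs]))
        ca_rmsd_tm = tfit.rmsd

    # binding-site heavy atoms, measured in the full-CA frame
    site: list[int] = []
    binding_site_rmsd = None
    if getattr(reference, "ligand_atoms", None):
        site = binding_site_residues(reference)
        r2m = {j: i for i, j in correspondence}
        m_atoms, r_atoms = [], []
        for j in site:
            i = r2m.get(j)
            if i is None:
                continue
            mres, rres = model.residues[i], reference.residues[j]
            for name, coord in rres.atoms.items():
                if name in mres.atoms:
                    r_atoms.append(coord)
                    m_atoms.append(mres.atoms[name])
        if m_atoms:
            moved = fit.apply(np.asarray(m_atoms, float))
            diff = moved - np.asarray(r_atoms, float)
            binding_site_rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))

    score = None
    if compute_tm_score and len(reference.residues) >= 17 and len(correspondence) >= 3:
        score = tm_score(model, reference, correspondence)
    return EvaluationReport(ca_rmsd_full, ca_rmsd_tm, binding_site_rmsd, score,
                            len(correspondence), site)


def _tm_score_kernel(d2: np.ndarray, L: int, d0: float) -> float:
    return float(np.sum(1.0 / (1.0 + d2 / d0 ** 2)) / L)


def tm_d0(L: int) -> float:
    if L < 17:
        raise ValueError("TM-score d0 is undefined for reference length < 17")
    return max(1.24 * (L - 15) ** (1.0 / 3.0) - 1.8, 0.5)


def tm_score(model, reference, correspondence: Sequence[tuple[int, int]] | None = None,
             superpose: bool = True) -> float:
    """Length-normalized structure-similarity score in (0, 1].

    Normalized by the reference length L. With ``superpose=False`` the
    score is evaluated at the given pose (no search), which exposes the
    raw formula: full coverage with every distance equal to d0 gives 0.5.
    """
    if correspondence is None:
        n = min(len(model.residues), len(reference.residues))
        correspondence = [(i, i) for i in range(n)
                          if model.residues[i].ca is not None
                          and reference.residues[i].ca is not None]
    correspondence = list(correspondence)
    L = len(reference.residues)
    d0 = tm_d0(L)
    if len(correspondence) < 3:
        raise ValueError("need at least 3 corresponded residues")
    mca = _ca_matrix(model, [i for i, _ in correspondence])
    rca = _ca_matrix(reference, [j for _, j in correspondence])
    n = len(correspondence)
    if not superpose:
        d2 = np.sum((mca - rca) ** 2, axis=1)
        return _tm_score_kernel(d2, L, d0)

    best = 0.0
    cut2 = d0 ** 2
    for frag in sorted({n, max(n // 2, 4), max(n // 4, 4)}, reverse=True):
        for start in range(0, n - frag + 1):
            sel = np.arange(start, start + frag)
            for _ in range(20):
                fit = kabsch_superpose(rca[sel], mca[sel])
                moved = fit.apply(mca)
                d2 = np.sum((moved - rca) ** 2, axis=1)
                best = max(best, _tm_score_kernel(d2, L, d0))
                new_sel = np.flatnonzero(d2 <= cut2)
                if len(new_sel) < 3:
                    new_sel = np.argsort(d2, kind="stable")[:3]
                if len(new_sel) == len(sel) and np.array_equal(new_sel, sel):
                    break
                sel = new_sel
    return best
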