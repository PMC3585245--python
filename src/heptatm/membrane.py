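"""Membrane Z-coordinate filtering of built models.

A model is rejected when any loop or terminal residue lies inside the
membrane slab (z_min <= z(CA) <= z_max, membrane normal along z). TM
helices cross the membrane by definition and H8 lies at the interface, so
both are exempt. The default slab is z in [-15, 15] Å, a typical
hydrophobic half-thickness; it is fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import MembraneSlab, StructureModel

#: Region labels the filter applies to; TM1..TM7 and H8 are exempt.
FILTERED_REGIONS = frozenset({"loop", "N-term", "C-term"})


@dataclass
class FilterVerdict:
    """Outcome of the Z filter for one model."""

    model_id: str
    offenders: list[tuple[int, str, float]] = field(default_factory=list)
    # (residue_index 0-based, region label, z of the offending atom)

    @property
    def passed(self) -> bool:
        return not self.offenders


def z_filter(model: StructureModel, slab: MembraneSlab | None = None,
             strict_backbone: bool = False) -> FilterVerdict:
    """Check that no loop or terminal residue enters the membrane slab.

    By default only CA atoms are tested; ``strict_backbone`` extends the
    check to all backbone atoms of the residue.
    """
    slab = slab or model.frame
    if len(model.region_labels) != len(model.residues):
        raise ValueError("model is missing region labels")
    offenders: list[tuple[int, str, float]] = []
    for i, (res, label) in enumerate(zip(model.residues, model.region_labels)):
        if label not in FILTERED_REGIONS:
            continue
        if strict_backbone:
            zs = [float(c[2]) for c in res.atoms.values()]
        else:
            zs = [float(res.ca[2])] if res.ca is not None else []
        for z in zs:
            if slab.contains(z):
                offenders.append((i, label, z))
                break
    return FilterVerdict(model.id, offenders)


def filter_ensemble(models: Sequence[StructureModel],
                    slab: MembraneSlab | None = None,
                    strict_backbone: bool = False,
                    ) -> tuple[list[StructureModel], list[FilterVerdict]]:
    """Order-preserving partition of an ensemble into passing models plus a
    per-model verdict report."""
    if not models:
        raise ValueError("no models to filter")
    verdicts = [z_filter(m, slab, strict_backbone) for m in models]
    passing = [m for m, v in zip(models, verdicts) if v.passed]
    return passing, verdicts
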