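"""Deterministic synthetic fixtures: ideal 7TM helix bundles, perturbed
template ensembles, simulated homolog families, and degraded alignments.

The bundle generator places ideal alpha-helices (1.5 Å rise per residue,
100° twist, CA radius 2.3 Å) on a circle with alternating up/down
orientation, connected by loops pushed outside the membrane slab, so a
clean bundle passes the Z filter by construction. Geometry is analytic and
seed-deterministic; it is meant to exercise superposition, averaging and
filtering, not to be a physically realistic membrane protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (GAP, MembraneSlab, ResidueEntry, SequenceRecord,
                         TemplateRecord)
from .pairwise import PairwiseAlignment
from .scoring import AMINO_ACIDS, blosum62

HELIX_RISE = 1.5      # Å per residue along the axis
HELIX_TWIST = 100.0   # degrees per residue
CA_RADIUS = 2.3       # Å, CA distance from the helix axis


@dataclass
class BundleSpec:
    """Geometry of a synthetic TM-helix bundle."""

    n_helices: int = 7
    residues_per_helix: int = 20
    loop_length: int = 6
    nterm_length: int = 3
    cterm_length: int = 3
    rise: float = HELIX_RISE
    twist: float = HELIX_TWIST
    bundle_radius: float = 12.0
    tilt: float = 0.0                      # degrees, applied to every helix
    bulges: list[tuple[int, int, int]] = field(default_factory=list)
    # (helix index 0-based, position within helix, +1 insertion / -1 deletion)
    slab: MembraneSlab = field(default_factory=MembraneSlab)
    loop_clearance: float = 3.0            # Å beyond the slab for loop CA
    with_ligand: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_helices, self.residues_per_helix, self.loop_length) <= 0:
            raise ValueError("geometry counts must be positive")
        if self.rise <= 0 or self.bundle_radius <= 0:
            raise ValueError("geometric parameters must be positive")
        for h, pos, delta in self.bulges:
            if not (0 <= h < self.n_helices):
                raise ValueError(f"bulge helix {h} out of range")
            if not (0 < pos < self.residues_per_helix - 1):
                raise ValueError(f"bulge position {pos} not inside its helix")
            if delta not in (1, -1):
                raise ValueError("bulge delta must be +1 or -1")


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=n))


def _backbone_atoms(ca: np.ndarray, axis_dir: float) -> dict[str, np.ndarray]:
    # fixed local offsets: adequate for round trips and RMSD bookkeeping
    return {
        "N": ca + np.array([-1.2, 0.4, -0.4 * axis_dir]),
        "CA": ca,
        "C": ca + np.array([1.2, 0.3, 0.4 * axis_dir]),
        "O": ca + np.array([1.6, 1.3, 0.5 * axis_dir]),
    }


def make_bundle(spec: BundleSpec) -> TemplateRecord:
    """Generate an ideal-geometry TM bundle as a TemplateRecord.

    TM CA atoms lie inside the slab, every loop/terminal CA strictly
    outside it; TM segments are annotated; output is bit-identical for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    slab = spec.slab
    helix_lengths = [spec.residues_per_helix] * spec.n_helices
    for h, _pos, delta in spec.bulges:
        helix_lengths[h] += delta

    coords: list[np.ndarray] = []
    dirs: list[float] = []
    labels: list[str] = []
    tm_segments: list[tuple[int, int]] = []

    z_top = slab.z_max + spec.loop_clearance
    z_bot = slab.z_min - spec.loop_clearance
    helix_origin_xy = []
    for h in range(spec.n_helices):
        ang = 2 * math.pi * h / spec.n_helices
        helix_origin_xy.append(np.array([spec.bundle_radius * math.cos(ang),
                                         spec.bundle_radius * math.sin(ang)]))

    def helix_coords(h: int) -> list[np.ndarray]:
        n_res = helix_lengths[h]
        up = h % 2 == 0
        span = (n_res - 1) * spec.rise
        z0 = -span / 2 if up else span / 2
        sign = 1.0 if up else -1.0
        tilt = math.radians(spec.tilt)
        out = []
        phase = float(rng.uniform(0, 2 * math.pi))
        for k in range(n_res):
            theta = phase + math.radians(spec.twist) * k
            local = np.array([CA_RADIUS * math.cos(theta),
                              CA_RADIUS * math.sin(theta),
                              z0 + sign * spec.rise * k])
            if tilt:
                c, s = math.cos(tilt), math.sin(tilt)
                local = np.array([c * local[0] + s * local[2], local[1],
                                  -s * local[0] + c * local[2]])
            out.append(local + np.array([*helix_origin_xy[h], 0.0]))
        return out

    def loop_coords(p: np.ndarray, q: np.ndarray, n: int, z_level: float,
                    ) -> list[np.ndarray]:
        out = []
        for k in range(1, n + 1):
            f = k / (n + 1)
            xy = (1 - f) * p[:2] + f * q[:2]
            out.append(np.array([xy[0], xy[1], z_level]))
        return out

    helices = [helix_coords(h) for h in range(spec.n_helices)]

    # N-terminus: above the first helix start (helix 0 runs upward, so its
    # start is at the bottom -> N-term sits below the slab)
    first = helices[0][0]
    nterm_z = z_bot if first[2] < 0 else z_top
    for k in range(spec.nterm_length, 0, -1):
        coords.append(np.array([first[0] - 2.0 * k, first[1], nterm_z]))
        dirs.append(1.0)
        labels.append("N-term")

    for h in range(spec.n_helices):
        start = len(coords)
        for ca in helices[h]:
            coords.append(ca)
            dirs.append(1.0 if h % 2 == 0 else -1.0)
            labels.append(f"TM{h + 1}")
        tm_segments.append((start, len(coords)))
        if h < spec.n_helices - 1:
            end = helices[h][-1]
            nxt = helices[h + 1][0]
            z_level = z_top if end[2] > 0 else z_bot
            for ca in loop_coords(end, nxt, spec.loop_length, z_level):
                coords.append(ca)
                dirs.append(1.0)
                labels.append("loop")

    last = helices[-1][-1]
    cterm_z = z_top if last[2] > 0 else z_bot
    for k in range(1, spec.cterm_length + 1):
        coords.append(np.array([last[0] + 2.0 * k, last[1], cterm_z]))
        dirs.append(1.0)
        labels.append("C-term")

    n_res = len(coords)
    seq = _random_sequence(rng, n_res)
    residues = [ResidueEntry(i + 1, seq[i], _backbone_atoms(coords[i], dirs[i]))
                for i in range(n_res)]
    ligand = []
    if spec.with_ligand:
        # a small ligand in the bundle cavity, mid-membrane, close enough to
        # the first helix to define a non-empty 5 Å binding site
        anchor_ca = helices[0][len(helices[0]) // 2]
        center = np.array([0.72 * anchor_ca[0], 0.72 * anchor_ca[1], anchor_ca[2]])
        for off in ([0.0, 0.0, 0.0], [1.2, 0.0, 0.4], [0.0, 1.2, -0.4]):
            ligand.append(center + np.array(off))
    rec = TemplateRecord(
        id=f"bundle{spec.seed}",
        sequence=SequenceRecord(f"bundle{spec.seed}", seq),
        residues=residues,
        tm_segments=tm_segments,
        membrane_frame=slab,
        ligand_atoms=ligand,
    )
    rec.validate()
    return rec


def perturb_structure(record: TemplateRecord, sigma: float, seed: int,
                      ) -> TemplateRecord:
    """Add i.i.d. Gaussian noise (sd *sigma* per coordinate) to every atom;
    sequence, labels and annotations are unchanged."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    residues = []
    for res in record.residues:
        atoms = {name: np.asarray(c, float) + rng.normal(0.0, sigma, size=3)
                 for name, c in res.atoms.items()}
        residues.append(ResidueEntry(res.number, res.name, atoms))
    out = TemplateRecord(
        id=f"{record.id}_p{seed}",
        sequence=SequenceRecord(f"{record.id}_p{seed}", record.sequence.residues),
        residues=residues,
        tm_segments=list(record.tm_segments),
        h8=record.h8,
        activation_state=record.activation_state,
        membrane_frame=record.membrane_frame,
        ligand_atoms=[np.asarray(c, float) + rng.normal(0.0, sigma, size=3)
                      for c in record.ligand_atoms],
        anchors=dict(record.anchors),
        ec2_cys=record.ec2_cys,
        tm3_cys=record.tm3_cys,
    )
    return out


@dataclass
class FamilySpec:
    """Parameters of a simulated homolog family."""

    root: SequenceRecord
    n_homologs: int = 5
    substitution_prob: float = 0.2
    indel_prob: float = 0.02
    indel_extend: float = 0.5      # geometric continuation probability
    temperature: float = 2.0       # softmax divisor for substitution proposals
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.substitution_prob, self.indel_prob, self.indel_extend):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def evolve_family(spec: FamilySpec) -> list[SequenceRecord]:
    """Derive homologs from a root sequence by per-site substitutions
    (proposals weighted by exponentiated substitution-matrix scores) and
    geometric-length indels. Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    S = blosum62().matrix[:20, :20]
    # proposal distribution per source residue, self excluded
    props = np.exp(S / spec.temperature)
    np.fill_diagonal(props, 0.0)
    props /= props.sum(axis=1, keepdims=True)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    out: list[SequenceRecord] = []
    for h in range(spec.n_homologs):
        chars: list[str] = []
        for c in spec.root.residues:
            if c in aa_index and rng.random() < spec.substitution_prob:
                k = rng.choice(20, p=props[aa_index[c]])
                chars.append(AMINO_ACIDS[k])
            else:
                chars.append(c)
            if rng.random() < spec.indel_prob:
                if rng.random() < 0.5 and len(chars) > 1:   # deletion run
                    while chars and len(chars) > 1:
                        chars.pop()
                        if rng.random() >= spec.indel_extend:
                            break
                else:                                       # insertion run
                    while True:
                        chars.append(AMINO_ACIDS[int(rng.integers(0, 20))])
                        if rng.random() >= spec.indel_extend:
                            break
        if not chars:
            chars = [spec.root.residues[0]]
        out.append(SequenceRecord(f"{spec.root.id}_hom{h + 1}", "".join(chars)))
    return out


def mutate_sequence(record: TemplateRecord, divergence: float, seed: int,
                    conserved: tuple[int, ...] = ()) -> TemplateRecord:
    """Substitute residues in place (no indels) with per-site probability
    *divergence*, leaving *conserved* positions untouched. Coordinates are
    unchanged, so structure-sequence correspondence is preserved."""
    rng = np.random.default_rng(seed)
    S = blosum62().matrix[:20, :20]
    props = np.exp(S / 2.0)
    np.fill_diagonal(props, 0.0)
    props /= props.sum(axis=1, keepdims=True)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    keep = set(conserved)
    chars = list(record.sequence.residues)
    for i, c in enumerate(chars):
        if i in keep or c not in aa_index:
            continue
        if rng.random() < divergence:
            chars[i] = AMINO_ACIDS[int(rng.choice(20, p=props[aa_index[c]]))]
    seq = "".join(chars)
    residues = [ResidueEntry(r.number, seq[i], dict(r.atoms))
                for i, r in enumerate(record.residues)]
    out = TemplateRecord(
        id=record.id, sequence=SequenceRecord(record.id, seq),
        residues=residues, tm_segments=list(record.tm_segments), h8=record.h8,
        activation_state=record.activation_state,
        membrane_frame=record.membrane_frame,
        ligand_atoms=[np.asarray(c, float) for c in record.ligand_atoms],
        anchors=dict(record.anchors), ec2_cys=record.ec2_cys,
        tm3_cys=record.tm3_cys)
    return out


def make_scenario(out_dir, seed: int = 0, n_templates: int = 2,
                  sigma: float = 1.0, divergence: float = 0.6,
                  with_ligand: bool = True, with_anchors: bool = True):
    """Write a complete synthetic modeling scenario to *out_dir*.

    The ground-truth bundle's sequence becomes the target; each template is
    the truth perturbed by coordinate noise with a substitutionally diverged
    sequence (anchor positions kept conserved). Returns
    (target_fasta_path, manifest_path, truth_record, template_records).
    """
    from pathlib import Path
    from .io_formats import write_fasta, write_manifest
    from .multitemplate import BW_ANCHOR_NAMES

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = make_bundle(BundleSpec(seed=seed, with_ligand=with_ligand))
    anchor_positions = {}
    if with_anchors:
        for k, (s, e) in enumerate(truth.tm_segments[:len(BW_ANCHOR_NAMES)]):
            anchor_positions[BW_ANCHOR_NAMES[k]] = (s + e) // 2
    templates = []
    for k in range(n_templates):
        tpl = perturb_structure(truth, sigma, seed=seed * 1000 + 7 * k + 1)
        tpl = mutate_sequence(tpl, divergence, seed=seed * 1000 + 7 * k + 2,
                              conserved=tuple(anchor_positions.values()))
        tpl.id = f"tpl{k + 1}"
        tpl.sequence.id = tpl.id
        tpl.anchors = dict(anchor_positions)
        templates.append(tpl)
    target_path = out / "target.fasta"
    write_fasta([SequenceRecord("target", truth.sequence.residues)], target_path)
    manifest_path = out / "templates.yaml"
    write_manifest(templates, manifest_path)
    write_pdb_truth = out / "truth.pdb"
    from .io_formats import write_pdb
    write_pdb(truth, write_pdb_truth)
    return target_path, manifest_path, truth, templates


def degrade_alignment(reference: PairwiseAlignment, n_errors: int, seed: int,
                      ) -> PairwiseAlignment:
    """Shift the template partner of up to *n_errors* randomly chosen
    target positions by ±1, keeping the partner map strictly increasing, and
    rebuild a valid alignment. Shifts that would break monotonicity are
    skipped, so the number of actually changed pairings may be smaller."""
    seq_a = reference.seq_a
    seq_b = reference.seq_b
    L = len(seq_a)
    if n_errors > L:
        raise ValueError("n_errors exceeds the target length")
    rng = np.random.default_rng(seed)
    partners = reference.partner_map()
    positions = rng.permutation(L)[:n_errors]
    for i in sorted(int(p) for p in positions):
        j = partners[i]
        delta = 1 if rng.random() < 0.5 else -1
        if j is None:
            continue
        new_j = j + delta
        if not (0 <= new_j < len(seq_b)):
            continue
        # a neighbor already paired with new_j loses its partner (the shift
        # displaces it); any other monotonicity violation skips the shift
        trial = list(partners)
        trial[i] = new_j
        for q in range(L):
            if q != i and trial[q] == new_j:
                trial[q] = None
        aligned = [(q, p) for q, p in enumerate(trial) if p is not None]
        if all(p1 < p2 for (_, p1), (_, p2) in zip(aligned, aligned[1:])):
            partners = trial
    return alignment_from_partner_map(seq_a, seq_b, partners,
                                      reference.id_a, reference.id_b)


def alignment_from_partner_map(seq_a: str, seq_b: str,
                               partners: list[int | None],
                               id_a: str = "a", id_b: str = "b",
                               ) -> PairwiseAlignment:
    """Rebuild a gapped alignment from a strictly increasing partner map."""
    ra, rb = [], []
    j = 0
    for i, p in enumerate(partners):
        if p is not None:
            while j < p:
                ra.append(GAP)
                rb.append(seq_b[j])
                j += 1
            ra.append(seq_a[i])
            rb.append(seq_b[j])
            j += 1
        else:
            ra.append(seq_a[i])
            rb.append(GAP)
    while j < len(seq_b):
        ra.append(GAP)
        rb.append(seq_b[j])
        j += 1
    return PairwiseAlignment("".join(ra), "".join(rb), 0.0, id_a, id_b)
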