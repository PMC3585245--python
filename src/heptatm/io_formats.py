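"""Core record types and file formats.

Covers the formats the modeling pipeline touches: FASTA sequences, gapped
FASTA alignments, minimal fixed-column PDB structures, and a YAML manifest
describing a template database (per template: PDB path, chain, TM-segment
annotations, activation state, membrane slab, optional conserved-residue
anchors).

Conventions
-----------
* Residue indexing is 0-based with half-open intervals internally; every
  file-facing representation (PDB numbering, manifest TM segments, anchors)
  is 1-based inclusive.
* The gap character is ``'-'``; ``'.'`` is rejected.
* Unknown residues map to ``'X'``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import yaml
from Bio import SeqIO
from Bio.SeqUtils import seq1, seq3

from .scoring import ALPHABET

GAP = "-"

_VALID_RESIDUES = set(ALPHABET)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """An ungapped protein sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MembraneSlab:
    """The membrane as a slab along the z axis: z_min <= z <= z_max."""

    z_min: float = -15.0
    z_max: float = 15.0

    def __post_init__(self) -> None:
        if not self.z_min < self.z_max:
            raise ValueError("slab requires z_min < z_max")

    def contains(self, z: float) -> bool:
        return self.z_min <= z <= self.z_max


@dataclass
class ResidueEntry:
    """One residue with named heavy-atom coordinates (Å)."""

    number: int                       # author residue number (1-based)
    name: str                         # 3-letter residue name
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")

    @property
    def one_letter(self) -> str:
        if len(self.name) == 1:
            return self.name if self.name in _VALID_RESIDUES else "X"
        code = seq1(self.name.capitalize())
        return code if code in _VALID_RESIDUES else "X"

    def heavy_coords(self) -> np.ndarray:
        """All atom coordinates as an (n, 3) array, insertion order."""
        return np.array([c for c in self.atoms.values()], dtype=float)


@dataclass
class TemplateRecord:
    """A template structure: sequence, backbone coordinates in the membrane
    frame, TM-segment annotations and optional ligand / anchor metadata."""

    id: str
    sequence: SequenceRecord
    residues: list[ResidueEntry]
    tm_segments: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    h8: tuple[int, int] | None = None
    activation_state: str = "unknown"
    membrane_frame: MembraneSlab = field(default_factory=MembraneSlab)
    ligand_atoms: list[np.ndarray] = field(default_factory=list)
    anchors: dict[str, int] = field(default_factory=dict)  # name -> 0-based index
    ec2_cys: int | None = None
    tm3_cys: int | None = None
    flags: list[str] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.sequence.residues)
        if len(self.residues) != n:
            raise ValueError(
                f"{self.id}: sequence length {n} != {len(self.residues)} residues")
        for i, res in enumerate(self.residues):
            if res.ca is None:
                raise ValueError(f"{self.id}: residue {i + 1} has no CA atom")
        last = 0
        for k, (s, e) in enumerate(self.tm_segments):
            if not (last <= s < e <= n):
                raise ValueError(
                    f"{self.id}: TM segment {k + 1} [{s},{e}) out of order/bounds")
            last = e
        if self.activation_state not in ("active", "inactive", "unknown"):
            raise ValueError(f"{self.id}: bad activation state")

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def region_labels(self) -> list[str]:
        """Per-residue region label derived from the TM/H8 annotations."""
        n = len(self.residues)
        labels = ["loop"] * n
        for k, (s, e) in enumerate(self.tm_segments):
            for i in range(s, e):
                labels[i] = f"TM{k + 1}"
        if self.h8 is not None:
            for i in range(self.h8[0], self.h8[1]):
                labels[i] = "H8"
        if self.tm_segments:
            first = self.tm_segments[0][0]
            stop = self.h8[1] if self.h8 is not None else self.tm_segments[-1][1]
            for i in range(first):
                labels[i] = "N-term"
            for i in range(stop, n):
                labels[i] = "C-term"
        return labels


REGION_NAMES = tuple(f"TM{i}" for i in range(1, 8)) + ("H8", "loop", "N-term", "C-term")


@dataclass
class StructureModel:
    """A built model: per-residue backbone coordinates with region labels,
    per-residue template coverage, and a membrane slab frame."""

    residues: list[ResidueEntry]
    region_labels: list[str]
    coverage: list[int]
    frame: MembraneSlab = field(default_factory=MembraneSlab)
    id: str = "model"

    def __post_init__(self) -> None:
        n = len(self.residues)
        if len(self.region_labels) != n or len(self.coverage) != n:
            raise ValueError("region_labels and coverage must match residues")
        bad = set(self.region_labels) - set(REGION_NAMES)
        if bad:
            raise ValueError(f"unknown region labels {sorted(bad)}")
        if n and not any(c >= 1 for c in self.coverage):
            raise ValueError("model has no covered residues")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(L, 3) CA coordinates; NaN rows for uncovered residues."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            if r.ca is not None:
                out[i] = r.ca
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _find_line(path: Path, needle: str) -> int:
    """1-based line number of the first line containing *needle* (0 if absent)."""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if needle in line:
            return lineno
    return 0


def read_fasta(path) -> list[SequenceRecord]:
    """Read ungapped sequences; residues are upper-cased and validated."""
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace(" ", "")
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        bad = set(residues) - _VALID_RESIDUES
        if bad:
            ch = sorted(bad)[0]
            lineno = _find_line(path, ch if ch != GAP else "-")
            raise ParseError(
                f"{path}:{lineno}: illegal residue character {ch!r} in "
                f"record {rec.id!r}")
        if not residues:
            lineno = _find_line(path, rec.id)
            raise ParseError(f"{path}:{lineno}: record {rec.id!r} has no residues")
        records.append(SequenceRecord(rec.id, residues, rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description and rec.description != rec.id else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_alignment_fasta(path) -> list[tuple[str, str]]:
    """Read a gapped-FASTA alignment as (id, gapped row) pairs.

    All rows must have the same column count; ungapping a row must yield a
    valid sequence.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        row = str(rec.seq).upper()
        if "." in row:
            raise ParseError(f"{path}: row {rec.id!r} uses '.' gaps; only '-' is supported")
        bad = set(row) - _VALID_RESIDUES - {GAP}
        if bad:
            raise ParseError(
                f"{path}: row {rec.id!r} has illegal character {sorted(bad)[0]!r}")
        rows.append((rec.id, row))
    if rows:
        width = len(rows[0][1])
        for rid, row in rows:
            if len(row) != width:
                raise ParseError(
                    f"{path}: ragged alignment — row {rid!r} has {len(row)} "
                    f"columns, expected {width}")
        for rid, row in rows:
            SequenceRecord(rid, row.replace(GAP, ""))  # validates non-empty
    return rows


def write_alignment_fasta(rows: Sequence[tuple[str, str]], path) -> None:
    path = Path(path)
    if rows:
        width = len(rows[0][1])
        for rid, row in rows:
            if len(row) != width:
                raise ValueError(f"row {rid!r} has inconsistent width")
    with path.open("w") as fh:
        for rid, row in rows:
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb_backbone(path, chain: str = "A") -> TemplateRecord:
    """Read the coordinate part of a template from a PDB file.

    Alternate locations resolve to the highest-occupancy atom (first
    encountered on ties). Non-water HETATM records are collected as ligand
    atoms. Residues missing a CA are kept and flagged, never dropped.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    st.setup_entities()
    if len(st) == 0:
        raise ParseError(f"{path}: no models in file")
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise ParseError(f"{path}: chain {chain!r} not found")

    residues: list[ResidueEntry] = []
    ligand_atoms: list[np.ndarray] = []
    flags: list[str] = []
    for res in ch:
        if res.seqid.icode not in (" ", "", "\x00"):
            raise ParseError(
                f"{path}: insertion code on residue {res.seqid.num}{res.seqid.icode} "
                "is not supported")
        is_het = res.het_flag == "H"
        if is_het:
            if res.name.strip().upper() not in _WATER_NAMES:
                for atom in res:
                    if atom.element.name != "H":
                        ligand_atoms.append(np.array(atom.pos.tolist()))
            continue
        best: dict[str, gemmi.Atom] = {}
        for atom in res:
            if atom.element.name == "H":
                continue
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                best[atom.name] = atom
        atoms = {name: np.array(a.pos.tolist()) for name, a in best.items()}
        entry = ResidueEntry(res.seqid.num, res.name, atoms)
        if entry.ca is None:
            flags.append(f"residue {res.seqid.num} ({res.name}) missing CA")
        residues.append(entry)
    if not residues:
        raise ParseError(f"{path}: chain {chain!r} has no ATOM records")
    residues.sort(key=lambda r: r.number)
    seq = "".join(r.one_letter for r in residues)
    rec = TemplateRecord(
        id=f"{path.stem}_{chain}",
        sequence=SequenceRecord(f"{path.stem}_{chain}", seq),
        residues=residues,
        ligand_atoms=ligand_atoms,
        flags=flags,
    )
    return rec


_MAX_COORD = 9999.999
_MIN_COORD = -999.999


def _atom_field(name: str) -> str:
    # columns 13-16; names up to 3 chars start in column 14
    return f" {name:<3s}" if len(name) < 4 else name[:4]


def write_pdb(model, path) -> None:
    """Write a model or template as fixed-column PDB ATOM records.

    Residues are renumbered 1..L on chain A with coordinates at 3 decimals.
    Region labels and coverage (when present) are emitted as REMARK 480
    lines so a written model is self-describing.
    """
    path = Path(path)
    residues = model.residues
    labels = getattr(model, "region_labels", None)
    if callable(labels):
        labels = None if isinstance(model, TemplateRecord) else labels()
    coverage = getattr(model, "coverage", None)
    lines: list[str] = []
    if labels is not None:
        for i, lab in enumerate(labels):
            cov = coverage[i] if coverage is not None else ""
            lines.append(f"REMARK 480 RES {i + 1:4d} REGION {lab:<6s} COV {cov}")
    serial = 1
    for i, res in enumerate(residues):
        resname = seq3(res.one_letter).upper() if len(res.name) != 3 else res.name.upper()
        for atom_name in (*BACKBONE_ATOMS,
                          *(n for n in res.atoms if n not in BACKBONE_ATOMS)):
            coord = res.atoms.get(atom_name)
            if coord is None:
                continue
            x, y, z = (float(v) for v in coord)
            for v in (x, y, z):
                if not (_MIN_COORD <= v <= _MAX_COORD) or not math.isfinite(v):
                    raise ValueError(
                        f"coordinate {v} of residue {i + 1} exceeds PDB field width")
            element = atom_name[0]
            lines.append(
                f"ATOM  {serial:5d} {_atom_field(atom_name)} {resname:>3s} A"
                f"{i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}")
            serial += 1
    for k, coord in enumerate(getattr(model, "ligand_atoms", []) or []):
        x, y, z = (float(v) for v in coord)
        lines.append(
            f"HETATM{serial:5d}  C{k + 1:<2d} LIG A{len(residues) + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C")
        serial += 1
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_model_pdb(path) -> StructureModel:
    """Read back a model written by :func:`write_pdb`, including the REMARK
    region labels and coverage."""
    path = Path(path)
    rec = read_pdb_backbone(path, chain="A")
    n = len(rec.residues)
    labels = ["loop"] * n
    coverage = [1] * n
    for line in path.read_text().splitlines():
        if line.startswith("REMARK 480 RES"):
            parts = line.split()
            idx = int(parts[3]) - 1
            labels[idx] = parts[5]
            if len(parts) > 7:
                coverage[idx] = int(parts[7])
    return StructureModel(rec.residues, labels, coverage, id=rec.id)


# ---------------------------------------------------------------------------
# template-database manifest
# ---------------------------------------------------------------------------

def load_manifest(path) -> list[TemplateRecord]:
    """Load a YAML template-database manifest.

    Each entry gives id, pdb path (relative to the manifest), chain,
    1-based inclusive TM segments, activation state, slab bounds, and
    optional anchors / disulfide annotations.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "templates" not in doc:
        raise ParseError(f"{path}: manifest must contain a 'templates' list")
    templates: list[TemplateRecord] = []
    for entry in doc["templates"]:
        pdb_path = path.parent / entry["pdb"]
        rec = read_pdb_backbone(pdb_path, entry.get("chain", "A"))
        rec.id = entry["id"]
        rec.sequence.id = entry["id"]
        rec.tm_segments = [(int(s) - 1, int(e)) for s, e in entry.get("tm_segments", [])]
        if entry.get("h8"):
            s, e = entry["h8"]
            rec.h8 = (int(s) - 1, int(e))
        rec.activation_state = entry.get("activation_state", "unknown")
        if entry.get("slab"):
            lo, hi = entry["slab"]
            rec.membrane_frame = MembraneSlab(float(lo), float(hi))
        rec.anchors = {str(k): int(v) - 1 for k, v in (entry.get("anchors") or {}).items()}
        if entry.get("ec2_cys") is not None:
            rec.ec2_cys = int(entry["ec2_cys"]) - 1
        if entry.get("tm3_cys") is not None:
            rec.tm3_cys = int(entry["tm3_cys"]) - 1
        rec.validate()
        templates.append(rec)
    if not templates:
        raise ParseError(f"{path}: manifest lists no templates")
    return templates


def write_manifest(templates: Sequence[TemplateRecord], path, pdb_dir=None) -> None:
    """Write templates (PDB files + YAML manifest) under *path*'s directory."""
    path = Path(path)
    pdb_dir = Path(pdb_dir) if pdb_dir is not None else path.parent
    entries = []
    for rec in templates:
        pdb_path = pdb_dir / f"{rec.id}.pdb"
        write_pdb(rec, pdb_path)
        entry = {
            "id": rec.id,
            "pdb": str(pdb_path.relative_to(path.parent)),
            "chain": "A",
            "tm_segments": [[s + 1, e] for s, e in rec.tm_segments],
            "activation_state": rec.activation_state,
            "slab": [rec.membrane_frame.z_min, rec.membrane_frame.z_max],
        }
        if rec.h8 is not None:
            entry["h8"] = [rec.h8[0] + 1, rec.h8[1]]
        if rec.anchors:
            entry["anchors"] = {k: v + 1 for k, v in rec.anchors.items()}
        if rec.ec2_cys is not None:
            entry["ec2_cys"] = rec.ec2_cys + 1
        if rec.tm3_cys is not None:
            entry["tm3_cys"] = rec.tm3_cys + 1
        entries.append(entry)
    path.write_text(yaml.safe_dump({"templates": entries}, sort_keys=False))
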