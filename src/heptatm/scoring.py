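"""Substitution-matrix scoring schemes for sequence and profile alignment.

The default scheme is BLOSUM62 with affine gap penalties open=10, extend=0.5
(ClustalW protein defaults). The 20 canonical amino acids are scored from the
matrix; the unknown residue 'X' scores 0 against everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

#: Canonical amino-acid alphabet, in the fixed order used by all numeric code.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
#: Full residue alphabet: 20 canonical letters plus 'X' for unknown.
ALPHABET = AMINO_ACIDS + "X"

AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    Parameters
    ----------
    matrix
        (21, 21) float array over :data:`ALPHABET`; symmetric; the 'X'
        row/column is zero.
    gap_open
        Non-negative penalty charged once per gap run.
    gap_extend
        Non-negative penalty charged per gapped position. A run of k gaps
        costs ``gap_open + k * gap_extend``.
    """

    matrix: np.ndarray
    gap_open: float = 10.0
    gap_extend: float = 0.5
    name: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError(f"matrix must be {len(ALPHABET)}x{len(ALPHABET)}")
        if not np.allclose(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        object.__setattr__(self, "matrix", m)

    def score(self, a: str, b: str) -> float:
        """Substitution score for a single residue pair."""
        return float(self.matrix[AA_INDEX[a], AA_INDEX[b]])

    def encode(self, residues: str) -> np.ndarray:
        """Map a residue string to alphabet indices."""
        try:
            return np.fromiter((AA_INDEX[c] for c in residues), dtype=np.intp,
                               count=len(residues))
        except KeyError as exc:  # pragma: no cover - guarded by io validation
            raise ValueError(f"residue {exc.args[0]!r} outside alphabet") from None


def _matrix_from_biopython(arr) -> np.ndarray:
    m = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = arr[a, b]
    return m  # X row/col stays 0


@lru_cache(maxsize=None)
def blosum62(gap_open: float = 10.0, gap_extend: float = 0.5) -> ScoringScheme:
    """The default BLOSUM62 scheme."""
    arr = substitution_matrices.load("BLOSUM62")
    return ScoringScheme(_matrix_from_biopython(arr), gap_open, gap_extend,
                         name="BLOSUM62")


def read_matrix(path, gap_open: float = 10.0, gap_extend: float = 0.5) -> ScoringScheme:
    """Read an NCBI-format substitution matrix file into a scheme."""
    with open(path) as fh:
        arr = substitution_matrices.read(fh)
    return ScoringScheme(_matrix_from_biopython(arr), gap_open, gap_extend,
                         name=str(path))
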