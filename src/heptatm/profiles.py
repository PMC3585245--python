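"""Sequence profiles and profile-profile alignment.

A profile summarizes a homolog family as per-column frequency vectors over
the 20 amino acids plus gap, indexed by an ungapped master (anchor)
sequence. Profile-profile alignment runs the same affine-gap dynamic
program as sequence alignment, but scores column pairs by the
substitution-matrix expectation

    score(c1, c2) = sum_a sum_b f1(a) f2(b) S(a, b)

over the 20 amino acids (PICASSO-style); a column's gap frequency scales
the penalty for gapping that column down proportionally, so columns that
are mostly gap in the family are cheap to gap. In the one-hot,
zero-pseudocount limit this reduces exactly to sequence-sequence
alignment, which the test suite exploits as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GAP, SequenceRecord
from .pairwise import (PairwiseAlignment, _as_residues, _pattern_to_rows,
                       align_position_scores, global_align)
from .scoring import ALPHABET, AMINO_ACIDS, ScoringScheme, blosum62

N_SYMBOLS = len(ALPHABET) + 1   # 20 aa + X + gap
GAP_IDX = N_SYMBOLS - 1


@dataclass
class Profile:
    """Per-column symbol frequencies for a homolog family.

    columns: (L, 22) array over ALPHABET + gap, each row summing to 1.
    depth: number of contributing sequences (master + homologs).
    anchor_sequence: the ungapped master sequence the columns index.
    """

    columns: np.ndarray
    depth: int
    anchor_sequence: SequenceRecord

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        if cols.ndim != 2 or cols.shape[1] != N_SYMBOLS:
            raise ValueError(f"columns must be (L, {N_SYMBOLS})")
        if cols.shape[0] != len(self.anchor_sequence.residues):
            raise ValueError("column count must equal anchor sequence length")
        if np.any(cols < 0):
            raise ValueError("negative frequency")
        if not np.allclose(cols.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile columns must sum to 1")
        self.columns = cols

    def __len__(self) -> int:
        return self.columns.shape[0]

    @property
    def aa_freqs(self) -> np.ndarray:
        """(L, 20) canonical amino-acid frequencies (X and gap excluded)."""
        return self.columns[:, :len(AMINO_ACIDS)]

    @property
    def gap_freqs(self) -> np.ndarray:
        return self.columns[:, GAP_IDX]

    def to_table(self, path) -> None:
        """Serialize as a tab-separated per-column frequency table."""
        header = "pos\tres\t" + "\t".join(ALPHABET) + "\tgap"
        lines = [header]
        for i, row in enumerate(self.columns):
            vals = "\t".join(f"{v:.6f}" for v in row)
            lines.append(f"{i + 1}\t{self.anchor_sequence.residues[i]}\t{vals}")
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")


def one_hot_profile(seq, pseudocount: float = 0.0) -> Profile:
    """Profile of a single sequence (used for sequence-vs-profile routes)."""
    return build_profile(seq, [], pseudocount=pseudocount)


def build_profile(master, homologs: Sequence, scheme: ScoringScheme | None = None,
                  pseudocount: float = 0.1) -> Profile:
    """Build a profile from a master sequence and its homolog set.

    Each homolog is globally aligned to the master (star topology); for
    every master position the residues (or gap) aligned to it are counted,
    the master's own residue included, then a uniform additive pseudocount
    is applied and the column normalized.
    """
    scheme = scheme or blosum62()
    mid, mres = _as_residues(master)
    master_rec = master if isinstance(master, SequenceRecord) else SequenceRecord(mid, mres)
    L = len(mres)
    counts = np.zeros((L, N_SYMBOLS))
    sym_index = {a: i for i, a in enumerate(ALPHABET)}
    for i, c in enumerate(mres):
        counts[i, sym_index[c]] += 1.0
    for hom in homologs:
        aln = global_align(master_rec, hom, scheme)
        partners = aln.partner_map()
        _, hres = _as_residues(hom)
        for i, j in enumerate(partners):
            if j is None:
                counts[i, GAP_IDX] += 1.0
            else:
                counts[i, sym_index[hres[j]]] += 1.0
    counts += pseudocount
    cols = counts / counts.sum(axis=1, keepdims=True)
    return Profile(cols, depth=1 + len(homologs), anchor_sequence=master_rec)


def _column_score_matrix(p1: Profile, p2: Profile, scheme: ScoringScheme) -> np.ndarray:
    S20 = scheme.matrix[:len(AMINO_ACIDS), :len(AMINO_ACIDS)]
    return p1.aa_freqs @ S20 @ p2.aa_freqs.T


def profile_profile_align(p_target: Profile, p_template: Profile,
                          scheme: ScoringScheme | None = None,
                          gap_open: float | None = None,
                          gap_extend: float | None = None) -> PairwiseAlignment:
    """Global affine-gap alignment of two profiles, projected onto their
    anchor sequences."""
    scheme = scheme or blosum62()
    go = scheme.gap_open if gap_open is None else gap_open
    ge = scheme.gap_extend if gap_extend is None else gap_extend
    S = _column_score_matrix(p_target, p_template, scheme)
    score, pattern = align_position_scores(
        S, go, ge,
        gap_scale_a=1.0 - p_target.gap_freqs,
        gap_scale_b=1.0 - p_template.gap_freqs)
    row_a, row_b = _pattern_to_rows(pattern, p_target.anchor_sequence.residues,
                                    p_template.anchor_sequence.residues)
    return PairwiseAlignment(row_a, row_b, score,
                             p_target.anchor_sequence.id,
                             p_template.anchor_sequence.id)


def score_alignment(alignment: PairwiseAlignment, p_target: Profile,
                    p_template: Profile, scheme: ScoringScheme | None = None,
                    ) -> float:
    """Score an existing alignment of the two profiles' anchor sequences.

    Sum of column-pair expectation scores minus affine gap costs (gap costs
    scaled by one minus the gap frequency of the gapped column); used to
    rank candidate alignments from the different generation routes.
    """
    scheme = scheme or blosum62()
    if alignment.seq_a != p_target.anchor_sequence.residues:
        raise ValueError("alignment row 1 does not match the target profile anchor")
    if alignment.seq_b != p_template.anchor_sequence.residues:
        raise ValueError("alignment row 2 does not match the template profile anchor")
    S = _column_score_matrix(p_target, p_template, scheme)
    scale_a = 1.0 - p_target.gap_freqs
    scale_b = 1.0 - p_template.gap_freqs
    total = 0.0
    i = j = 0
    prev_gap_a = prev_gap_b = False
    for ca, cb in zip(alignment.row_a, alignment.row_b):
        if ca == GAP:      # consuming template column j
            cost = scheme.gap_extend + (0.0 if prev_gap_a else scheme.gap_open)
            total -= cost * scale_b[j]
            j += 1
            prev_gap_a, prev_gap_b = True, False
        elif cb == GAP:    # consuming target column i
            cost = scheme.gap_extend + (0.0 if prev_gap_b else scheme.gap_open)
            total -= cost * scale_a[i]
            i += 1
            prev_gap_a, prev_gap_b = False, True
        else:
            total += S[i, j]
            i += 1
            j += 1
            prev_gap_a = prev_gap_b = False
    return float(total)
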