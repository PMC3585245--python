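"""Global pairwise sequence alignment and template selection.

Implements the Gotoh three-state dynamic program for global alignment with
a substitution matrix and affine gap penalties (a gap run of length k costs
``gap_open + k * gap_extend``; terminal gaps are penalized), the
percent-identity statistic used to rank templates, and the rule that picks
one template at high identity (> 50) and the two most similar templates
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GAP, SequenceRecord, TemplateRecord
from .scoring import ScoringScheme, blosum62

NEG = -1e30  # effectively -inf, safe for additions


@dataclass
class PairwiseAlignment:
    """Two gapped rows of equal length over a common column set."""

    row_a: str
    row_b: str
    score: float
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows differ in length")
        for ca, cb in zip(self.row_a, self.row_b):
            if ca == GAP and cb == GAP:
                raise ValueError("gap-gap column in alignment")

    @property
    def seq_a(self) -> str:
        return self.row_a.replace(GAP, "")

    @property
    def seq_b(self) -> str:
        return self.row_b.replace(GAP, "")

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        """(i, j) 0-based residue-index pairs of non-gap columns."""
        pairs = []
        i = j = 0
        for ca, cb in zip(self.row_a, self.row_b):
            if ca != GAP and cb != GAP:
                pairs.append((i, j))
            if ca != GAP:
                i += 1
            if cb != GAP:
                j += 1
        return pairs

    def partner_map(self) -> list[int | None]:
        """For each residue of sequence A: the aligned residue index of
        sequence B, or None when aligned to a gap."""
        out: list[int | None] = [None] * len(self.seq_a)
        for i, j in self.aligned_pairs:
            out[i] = j
        return out

    def __len__(self) -> int:
        return len(self.row_a)


def score_pair_columns(alignment: PairwiseAlignment, scheme: ScoringScheme) -> float:
    """Re-score an alignment under the affine-gap model (independent of DP)."""
    total = 0.0
    prev_gap_a = prev_gap_b = False
    for ca, cb in zip(alignment.row_a, alignment.row_b):
        if ca == GAP:
            total -= scheme.gap_extend + (0.0 if prev_gap_a else scheme.gap_open)
            prev_gap_a, prev_gap_b = True, False
        elif cb == GAP:
            total -= scheme.gap_extend + (0.0 if prev_gap_b else scheme.gap_open)
            prev_gap_a, prev_gap_b = False, True
        else:
            total += scheme.score(ca, cb)
            prev_gap_a = prev_gap_b = False
    return total


def _as_residues(seq) -> tuple[str, str]:
    if isinstance(seq, SequenceRecord):
        return seq.id, seq.residues
    return "seq", str(seq)


def align_position_scores(S: np.ndarray, gap_open: float, gap_extend: float,
                          gap_scale_a: np.ndarray | None = None,
                          gap_scale_b: np.ndarray | None = None,
                          ) -> tuple[float, str]:
    """Gotoh global alignment over a precomputed position-score matrix.

    Parameters
    ----------
    S
        (n, m) array of column-column substitution scores.
    gap_scale_a, gap_scale_b
        Optional per-position multipliers for the cost of gapping position i
        of sequence a (resp. b); used by profile alignment where mostly-gap
        columns are cheap to gap. Defaults to 1 everywhere.

    Returns (score, pattern) where the pattern is a string over
    {'M','A','B'}: M = aligned column, A = column consuming a only (gap in
    b), B = column consuming b only.

    Traceback tie-break: diagonal > gap in b (consume a) > gap in a.
    """
    n, m = S.shape
    ga = np.ones(n) if gap_scale_a is None else np.asarray(gap_scale_a, float)
    gb = np.ones(m) if gap_scale_b is None else np.asarray(gap_scale_b, float)
    # M[i,j]: best ending with a_i aligned to b_j
    # X[i,j]: best ending with a_i aligned to gap (gap in b)
    # Y[i,j]: best ending with b_j aligned to gap (gap in a)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        open_cost = (gap_open + gap_extend) * ga[i - 1]
        ext_cost = gap_extend * ga[i - 1]
        X[i, 0] = (0.0 if i == 1 else X[i - 1, 0]) - (open_cost if i == 1 else ext_cost)
    for j in range(1, m + 1):
        open_cost = (gap_open + gap_extend) * gb[j - 1]
        ext_cost = gap_extend * gb[j - 1]
        Y[0, j] = (0.0 if j == 1 else Y[0, j - 1]) - (open_cost if j == 1 else ext_cost)
    for i in range(1, n + 1):
        xo = (gap_open + gap_extend) * ga[i - 1]
        xe = gap_extend * ga[i - 1]
        Mi1 = M[i - 1]
        Xi1 = X[i - 1]
        Yi1 = Y[i - 1]
        Mi = M[i]
        Xi = X[i]
        Yi = Y[i]
        Si = S[i - 1]
        for j in range(1, m + 1):
            best_prev = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = best_prev + Si[j - 1]
            Xi[j] = max(Mi1[j] - xo, Xi1[j] - xe, Yi1[j] - xo)
            yo = (gap_open + gap_extend) * gb[j - 1]
            ye = gap_extend * gb[j - 1]
            Yi[j] = max(Mi[j - 1] - yo, Xi[j - 1] - yo, Yi[j - 1] - ye)
    # traceback, deterministic: M > X (gap in b) > Y (gap in a)
    i, j = n, m
    state = max(((M[n, m], "M"), (X[n, m], "X"), (Y[n, m], "Y")),
                key=lambda t: (t[0], -"MXY".index(t[1])))[1]
    score = {"M": M[n, m], "X": X[n, m], "Y": Y[n, m]}[state]
    ops: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            ops.append("M")
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for cand, lbl in ((M[i, j], "M"), (X[i, j], "X"), (Y[i, j], "Y")):
                if abs(cand - target) < eps:
                    state = lbl
                    break
        elif state == "X":
            ops.append("A")
            xo = (gap_open + gap_extend) * ga[i - 1]
            xe = gap_extend * ga[i - 1]
            val = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - xo - val) < eps:
                state = "M"
            elif abs(X[i, j] - xe - val) < eps:
                state = "X"
            else:
                state = "Y"
        else:
            ops.append("B")
            yo = (gap_open + gap_extend) * gb[j - 1]
            ye = gap_extend * gb[j - 1]
            val = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - yo - val) < eps:
                state = "M"
            elif abs(X[i, j] - yo - val) < eps:
                state = "X"
            else:
                state = "Y"
    ops.reverse()
    return float(score), "".join(ops)


def _pattern_to_rows(pattern: str, a: str, b: str) -> tuple[str, str]:
    ra, rb = [], []
    i = j = 0
    for op in pattern:
        if op == "M":
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif op == "A":
            ra.append(a[i]); rb.append(GAP); i += 1
        else:
            ra.append(GAP); rb.append(b[j]); j += 1
    return "".join(ra), "".join(rb)


def global_align(seq_a, seq_b, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment of two sequences (Gotoh affine-gap DP)."""
    scheme = scheme or blosum62()
    id_a, a = _as_residues(seq_a)
    id_b, b = _as_residues(seq_b)
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    ia = scheme.encode(a)
    ib = scheme.encode(b)
    S = scheme.matrix[np.ix_(ia, ib)]
    score, pattern = align_position_scores(S, scheme.gap_open, scheme.gap_extend)
    row_a, row_b = _pattern_to_rows(pattern, a, b)
    return PairwiseAlignment(row_a, row_b, score, id_a, id_b)


def percent_identity(alignment: PairwiseAlignment) -> float:
    """100 x identical aligned pairs / length of the shorter sequence."""
    ident = sum(1 for ca, cb in zip(alignment.row_a, alignment.row_b)
                if ca == cb and ca != GAP)
    denom = min(len(alignment.seq_a), len(alignment.seq_b))
    return 100.0 * ident / denom


IDENTITY_THRESHOLD = 50.0  # strict "above 50" -> single template


def select_templates(target, template_db: Sequence[TemplateRecord],
                     scheme: ScoringScheme | None = None,
                     max_low_id_templates: int = 2,
                     activation_state: str | None = None,
                     ) -> list[tuple[TemplateRecord, float]]:
    """Pick templates for a target by percent identity.

    If the best identity is strictly above 50, that single template is
    returned; otherwise the ``max_low_id_templates`` most similar templates
    are returned in descending identity (ties broken by template id).
    Returns (template, identity) pairs.
    """
    scheme = scheme or blosum62()
    if activation_state is not None:
        template_db = [t for t in template_db
                       if t.activation_state == activation_state]
    if not template_db:
        raise ValueError("template database is empty")
    scored = []
    for tpl in template_db:
        aln = global_align(target, tpl.sequence, scheme)
        scored.append((tpl, percent_identity(aln)))
    scored.sort(key=lambda t: (-t[1], t[0].id))
    if scored[0][1] > IDENTITY_THRESHOLD:
        return scored[:1]
    return scored[:max_low_id_templates]
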