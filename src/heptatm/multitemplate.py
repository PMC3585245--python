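"""Anchored realignment, reconciliation into a multi-template alignment,
alignment-route selection, and the alignment-accuracy statistic.

Anchored realignment pins conserved residue pairs (by default the
Ballesteros-Weinstein x.50 positions of the seven TM helices, plus the
conserved EC2/TM3 cysteine pair when annotated) as fixed aligned columns
and realigns each intervening segment independently and optimally.

Reconciliation merges several target-template pairwise alignments into one
multi-row alignment using the target as the spine: template insertions
relative to the target become target-gap columns, placed in template-list
order; projecting the result back onto any single template recovers that
template's input pairwise alignment exactly.

Alignment accuracy against a reference (e.g. structure-derived) alignment
is the fraction of target positions whose partner — a template residue
index, or gap — is identical in both alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .io_formats import GAP, SequenceRecord
from .pairwise import PairwiseAlignment, _as_residues, global_align
from .scoring import ScoringScheme, blosum62

logger = logging.getLogger(__name__)

#: Class-A conserved positions used as default anchors, one per TM helix.
BW_ANCHOR_NAMES = ("N1.50", "D2.50", "R3.50", "W4.50", "P5.50", "P6.50", "P7.50")

#: Fixed preference order of the alignment-generation routes.
ROUTE_ORDER = ("psa", "msa", "profile")


@dataclass(frozen=True)
class Anchor:
    name: str
    target_index: int
    template_index: int


@dataclass
class AnchorSet:
    """Residue pairs that must appear as aligned columns."""

    anchors: list[Anchor] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_t = prev_p = -1
        for a in self.anchors:
            if a.target_index <= prev_t or a.template_index <= prev_p:
                raise ValueError(
                    f"anchors out of order at {a.name}: indices must be "
                    "strictly increasing in both sequences")
            prev_t, prev_p = a.target_index, a.template_index

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self):
        return iter(self.anchors)

    def validate_bounds(self, target_len: int, template_len: int) -> None:
        for a in self.anchors:
            if not (0 <= a.target_index < target_len):
                raise ValueError(f"anchor {a.name}: target index out of bounds")
            if not (0 <= a.template_index < template_len):
                raise ValueError(f"anchor {a.name}: template index out of bounds")


def locate_anchors(target, template_record, initial_alignment: PairwiseAlignment,
                   window: int = 5) -> AnchorSet:
    """Project a template's annotated anchors onto the target.

    For each annotated anchor the target position implied by the initial
    alignment is searched within ±window residues for the template's anchor
    residue; anchors without a match are dropped with a warning.
    """
    _, tres = _as_residues(target)
    annotations = dict(template_record.anchors)
    if template_record.ec2_cys is not None:
        annotations.setdefault("EC2-Cys", template_record.ec2_cys)
    partners = initial_alignment.partner_map()
    # invert: template index -> target index
    t2a = {j: i for i, j in enumerate(partners) if j is not None}
    found: list[Anchor] = []
    for name in sorted(annotations, key=lambda n: annotations[n]):
        j = annotations[name]
        tpl_res = template_record.sequence.residues[j]
        # implied target position: nearest aligned template position
        implied = None
        for dj in range(0, len(template_record.sequence.residues)):
            for jj in (j - dj, j + dj):
                if jj in t2a:
                    implied = t2a[jj] + (j - jj)
                    break
            if implied is not None:
                break
        if implied is None:
            logger.warning("anchor %s: no aligned neighborhood; dropped", name)
            continue
        hit = None
        for d in range(window + 1):
            for cand in (implied - d, implied + d):
                if 0 <= cand < len(tres) and tres[cand] == tpl_res:
                    hit = cand
                    break
            if hit is not None:
                break
        if hit is None:
            logger.warning("anchor %s (%s at template %d): no match within ±%d "
                           "of target %d; dropped", name, tpl_res, j + 1,
                           window, implied + 1)
            continue
        found.append(Anchor(name, hit, j))
    # enforce mutual ordering: greedily keep anchors increasing in both
    kept: list[Anchor] = []
    for a in found:
        if kept and (a.target_index <= kept[-1].target_index
                     or a.template_index <= kept[-1].template_index):
            logger.warning("anchor %s conflicts with %s; dropped", a.name,
                           kept[-1].name)
            continue
        kept.append(a)
    return AnchorSet(kept)


Aligner = Callable[[str, str], PairwiseAlignment]


def _align_segment(a: str, b: str, aligner: Aligner,
                   scheme: ScoringScheme) -> tuple[str, str, float]:
    if not a and not b:
        return "", "", 0.0
    if not a:
        return GAP * len(b), b, -(scheme.gap_open + scheme.gap_extend * len(b))
    if not b:
        return a, GAP * len(a), -(scheme.gap_open + scheme.gap_extend * len(a))
    aln = aligner(a, b)
    return aln.row_a, aln.row_b, aln.score


def anchored_realign(target, template, anchors: AnchorSet,
                     aligner: Aligner | None = None,
                     scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Realign two sequences with anchor pairs fixed as aligned columns.

    Each inter-anchor segment (and both flanks) is aligned independently by
    the supplied aligner; the pieces and anchor columns are concatenated.
    With an empty anchor set this is exactly the plain global alignment.
    """
    scheme = scheme or blosum62()
    if aligner is None:
        aligner = lambda a, b: global_align(a, b, scheme)
    id_a, a = _as_residues(target)
    id_b, b = _as_residues(template)
    anchors.validate_bounds(len(a), len(b))
    if len(anchors) == 0:
        aln = aligner(a, b)
        return PairwiseAlignment(aln.row_a, aln.row_b, aln.score, id_a, id_b)
    rows_a: list[str] = []
    rows_b: list[str] = []
    total = 0.0
    prev_i = prev_j = 0
    for anchor in anchors:
        seg_a = a[prev_i:anchor.target_index]
        seg_b = b[prev_j:anchor.template_index]
        ra, rb, s = _align_segment(seg_a, seg_b, aligner, scheme)
        rows_a.append(ra)
        rows_b.append(rb)
        total += s
        rows_a.append(a[anchor.target_index])
        rows_b.append(b[anchor.template_index])
        total += scheme.score(a[anchor.target_index], b[anchor.template_index])
        prev_i = anchor.target_index + 1
        prev_j = anchor.template_index + 1
    ra, rb, s = _align_segment(a[prev_i:], b[prev_j:], aligner, scheme)
    rows_a.append(ra)
    rows_b.append(rb)
    total += s
    return PairwiseAlignment("".join(rows_a), "".join(rows_b), total, id_a, id_b)


@dataclass
class MultiTemplateAlignment:
    """One target row plus N template rows over a common column set."""

    target_id: str
    target_row: str
    template_ids: list[str]
    template_rows: list[str]

    def __post_init__(self) -> None:
        width = len(self.target_row)
        if len(self.template_ids) != len(self.template_rows):
            raise ValueError("template ids and rows differ in number")
        for tid, row in zip(self.template_ids, self.template_rows):
            if len(row) != width:
                raise ValueError(f"template row {tid!r} has wrong width")
        for k in range(width):
            if self.target_row[k] == GAP and all(
                    row[k] == GAP for row in self.template_rows):
                raise ValueError(f"all-gap column {k}")

    @property
    def target_sequence(self) -> str:
        return self.target_row.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.target_row)

    @property
    def n_templates(self) -> int:
        return len(self.template_ids)

    def project(self, template_id: str) -> PairwiseAlignment:
        """Pairwise target-template alignment recovered by deleting the
        other template rows and all resulting all-gap columns."""
        k = self.template_ids.index(template_id)
        row = self.template_rows[k]
        ra, rb = [], []
        for ct, cr in zip(self.target_row, row):
            if ct == GAP and cr == GAP:
                continue
            ra.append(ct)
            rb.append(cr)
        return PairwiseAlignment("".join(ra), "".join(rb), 0.0,
                                 self.target_id, template_id)

    def column_map(self) -> list[list[tuple[str, int]]]:
        """Per target residue: the (template_id, template_residue_index)
        pairs aligned to it."""
        out: list[list[tuple[str, int]]] = [[] for _ in self.target_sequence]
        counters = [0] * self.n_templates
        ti = 0
        for k, ct in enumerate(self.target_row):
            for t in range(self.n_templates):
                cr = self.template_rows[t][k]
                if cr != GAP:
                    if ct != GAP:
                        out[ti].append((self.template_ids[t], counters[t]))
                    counters[t] += 1
            if ct != GAP:
                ti += 1
        return out

    def coverage(self) -> list[int]:
        """Number of non-gap template rows at each target residue."""
        return [len(entries) for entries in self.column_map()]


def reconcile_alignments(target, pairwise_alignments: Sequence[PairwiseAlignment],
                         ) -> MultiTemplateAlignment:
    """Merge per-template pairwise alignments into one multi-template
    alignment with the target as the spine.

    Template insertions relative to the target become target-gap columns,
    emitted in template-list order then left-to-right; projecting back onto
    any template recovers its input alignment exactly.
    """
    tid, tres = _as_residues(target)
    if not pairwise_alignments:
        raise ValueError("no alignments to reconcile")
    for aln in pairwise_alignments:
        if aln.seq_a != tres:
            raise ValueError(
                f"alignment {aln.id_b!r} has a different target sequence")
    L = len(tres)
    n = len(pairwise_alignments)
    # per template: partner per target residue, and insertion runs keyed by
    # the number of target residues consumed before the run
    partners: list[list[int | None]] = []
    insertions: list[dict[int, list[int]]] = []
    for aln in pairwise_alignments:
        partners.append(aln.partner_map())
        ins: dict[int, list[int]] = {}
        i = j = 0
        for ca, cb in zip(aln.row_a, aln.row_b):
            if ca == GAP:
                ins.setdefault(i, []).append(j)
                j += 1
            else:
                if cb != GAP:
                    j += 1
                i += 1
        insertions.append(ins)

    target_row: list[str] = []
    template_rows: list[list[str]] = [[] for _ in range(n)]
    seqs_b = [aln.seq_b for aln in pairwise_alignments]

    def emit_insertions(pos: int) -> None:
        for t in range(n):
            for j in insertions[t].get(pos, ()):
                target_row.append(GAP)
                for u in range(n):
                    template_rows[u].append(seqs_b[u][j] if u == t else GAP)

    for i in range(L):
        emit_insertions(i)
        target_row.append(tres[i])
        for t in range(n):
            j = partners[t][i]
            template_rows[t].append(seqs_b[t][j] if j is not None else GAP)
    emit_insertions(L)

    return MultiTemplateAlignment(
        target_id=tid,
        target_row="".join(target_row),
        template_ids=[aln.id_b for aln in pairwise_alignments],
        template_rows=["".join(r) for r in template_rows])


def choose_best_alignment(candidates: Sequence[tuple[str, PairwiseAlignment]],
                          p_target, p_template,
                          scheme: ScoringScheme | None = None,
                          ) -> tuple[str, PairwiseAlignment]:
    """Pick the best candidate alignment under the profile scoring scheme.

    Candidates are (route, alignment) pairs from the PSA / MSA / profile
    routes; ties resolve to the earlier route in that fixed order.
    """
    from .profiles import score_alignment
    if not candidates:
        raise ValueError("no candidate alignments")
    scheme = scheme or blosum62()

    def route_rank(route: str) -> int:
        return ROUTE_ORDER.index(route) if route in ROUTE_ORDER else len(ROUTE_ORDER)

    best = None
    best_key = None
    for route, aln in candidates:
        s = score_alignment(aln, p_target, p_template, scheme)
        key = (-s, route_rank(route))
        if best_key is None or key < best_key:
            best, best_key = (route, aln), key
    return best


def alignment_accuracy(test: PairwiseAlignment, reference: PairwiseAlignment,
                       target_length: int | None = None) -> float:
    """Fraction of target positions whose partner (template residue index,
    or gap) agrees with the reference alignment."""
    if test.seq_a != reference.seq_a or test.seq_b != reference.seq_b:
        raise ValueError("test and reference align different sequences")
    L = target_length if target_length is not None else len(test.seq_a)
    tp = sum(1 for p, q in zip(test.partner_map(), reference.partner_map())
             if p == q)
    return tp / L
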