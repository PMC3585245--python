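# Methods

This note records the models, conventions and deliberate simplifications
behind `heptatm`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic fixtures do and do not
establish about real receptors.

## Sequence alignment

Global alignment uses the Gotoh three-state recursion with BLOSUM62 and
affine gap penalties. A gap run of length k costs `gap_open + k *
gap_extend`, with defaults open = 10, extend = 0.5 (ClustalW protein
defaults; the identity statistic is likewise normalized by the shorter
ungapped sequence, the ClustalW convention). Terminal gaps are penalized:
targets and 7TM templates have comparable spans, and a fully global model
keeps the optimum unambiguous for testing. Traceback ties resolve
diagonal → gap-in-template → gap-in-target, so outputs are deterministic.
The unknown residue `X` scores 0 against everything. Correctness is pinned
by two independent oracles: exhaustive enumeration of all global
alignments for short sequences, and Biopython's `PairwiseAligner` for long
ones.

Percent identity drives template selection: strictly above 50 → one
template, otherwise the two most similar (ties by template id), optionally
after filtering the database by activation state. The threshold is strict
by design; identity exactly 50 selects two templates.

## Profiles

A profile is a column-stochastic matrix over 21 symbols (20 amino acids +
gap) anchored on an ungapped master sequence. It is built from star-
topology pairwise alignments of each homolog to the master — deterministic
and cheap, at the cost of ignoring homolog-homolog consistency — with a
uniform additive pseudocount (default 0.1) before normalization.

Profile columns are compared by the substitution-matrix expectation
(PICASSO-style) over the 20 amino acids. This choice has a property the
test suite leans on: with one-hot columns and zero pseudocount,
profile-profile alignment reduces *exactly* to sequence-sequence
alignment, giving a free oracle. Gap penalties at a column are scaled by
one minus that column's gap frequency, so positions the family mostly
gaps are cheap to gap; the scaling vanishes in the one-hot limit. The
same expectation-plus-scaled-gap-cost functional re-scores candidate
alignments from the three generation routes (PSA, sequence-vs-profile,
profile-vs-profile); ties resolve to the earlier route in that order.

## Anchored realignment

Anchors are residue pairs forced to occupy their own aligned column. The
default inventory is the class-A Ballesteros–Weinstein x.50 positions
(N1.50, D2.50, R3.50, W4.50, P5.50, P6.50, P7.50) plus the conserved
EC2/TM3 cysteines when annotated; all are user-overridable through the
template manifest. A template's annotated anchor is located on the target
by searching for the same residue within ±5 positions of the position the
initial alignment implies; unmatched or mutually crossing anchors are
dropped with a warning rather than forced. Between anchors (and on both
flanks) segments are aligned independently and optimally, so the
concatenated result is the constrained optimum for the given anchor set.

## Reconciliation

Per-template pairwise alignments are merged target-spined: target residues
index the columns, template insertions become target-gap columns emitted
in template-list order then left-to-right, keyed by the number of target
residues consumed. This specific bookkeeping makes the merge lossless —
deleting the other rows and the resulting all-gap columns reproduces each
input alignment byte-for-byte — which is the property that lets helix
bulges travel through the pipeline: a one-residue gap inside one
template's TM helix stays in that row only, neither propagated to other
templates nor erased. An all-pairs-consistent merge was the open
alternative; the target-spined rule was chosen because its projection
property is exact and testable.

## Model building

Model building is weighted coordinate averaging, a deliberate desk-scale
surrogate for restraint-based optimization: templates 2..N are Kabsch-
superposed onto template 1 over the CA atoms of columns where every
template is non-gap and inside an annotated TM segment (the stable core),
then each covered target residue's backbone atoms are the weighted mean of
the aligned template atoms. Weights default to normalized target-template
percent identity, mirroring the identity-driven selection rule. Residues
no template covers are emitted without coordinates and flagged — loop
reconstruction is out of scope, and inventing coordinates would corrupt
the filter and the metrics downstream. Region labels transfer from the
highest-weight covering template; uncovered flanks become termini.

The payoff is quantitative: for k templates carrying independent Gaussian
coordinate noise, the averaged backbone's RMSD to the truth contracts by
1/√k. The acceptance suite measures this with k ∈ {2, 3}, σ = 1 Å,
200-residue chains and 20 replicates, and requires the measured ratio
within 15% of 1/√k — sampling noise at that problem size sits well inside
that band.

## Membrane filter

Models are assumed pre-oriented with the membrane normal along z (as
template databases in this domain store them). A residue offends when its
region label is loop/N-term/C-term and its Cα has
`z_min ≤ z ≤ z_max`; TM helices cross the slab by definition and H8 is
treated as an interfacial helix and exempted. The default slab is
z ∈ [−15, 15] Å, a typical hydrophobic half-thickness; both bounds and a
stricter all-backbone mode are configurable. The filter hard-rejects with
a full offender list rather than down-ranking; the verdict is invariant to
in-plane rigid motions and monotone in the slab (growing the membrane can
only create offenders).

## Evaluation

Full-chain Cα RMSD is measured after a Kabsch fit on all corresponded Cα;
TM-region RMSD after a fit on TM-labeled residues only. The binding site
is the residue set with any heavy atom within 5 Å of any ligand heavy atom
in the reference; its RMSD is measured over heavy atoms in the full-chain
frame (measured, not re-fitted — the site should not be allowed to hide a
mis-placed helix). The 5 Å criterion is heavy-atom/heavy-atom; hydrogens
are never present on backbone-only models.

The TM-score is computed natively over a *given* residue correspondence
(models share the target sequence, so no structure-alignment search is
needed): d₀ = 1.24·(L−15)^⅓ − 1.8 clamped below at 0.5, L the reference
length, with the published heuristic — seed fragments of lengths L, L/2,
L/4 slid along the chain, each refined by re-fitting on residues within d₀
until the selection is stable, keeping the best score seen. References
shorter than 17 residues are rejected (d₀ undefined). A full-coverage pose
with every distance equal to d₀ scores exactly 0.5.

## Synthetic fixtures

Bundles use ideal helix geometry (rise 1.5 Å, twist 100°, Cα radius
2.3 Å) on a circle of radius 12 Å with alternating up/down orientation,
20 residues per helix (span 28.5 Å, inside the ±15 Å slab), 6-residue
loops placed 3 Å beyond the slab bound, and 3-residue termini. Loop
placement guarantees a clean pass/fail surface for the filter; bulge
directives insert or delete one helix residue. Sequences are uniform
random; homolog families evolve by per-site substitution (proposals
softmax-weighted by BLOSUM62 scores, temperature 2) and geometric-length
indels. Alignment degradation shifts randomly chosen partners by ±1,
displacing a colliding neighbor's pairing to gap and skipping shifts that
would break monotonicity, so accuracy against the original is exactly the
recounted fraction of unchanged pairings. Every generator takes an
explicit seed and owns its RNG stream; reruns are bit-identical.

What passing on these fixtures shows: the pipeline's bookkeeping and
numerics are exact, and averaging behaves as the noise model predicts.
What it does not show: performance on real receptors, where template
errors are correlated (shared fold, systematic helix shifts), loops are
structured rather than analytic, and profile quality depends on real
evolutionary depth. The fixtures deliberately trade realism for exactness.

## Problem sizes and determinism

Default scenarios use 182-residue bundles and two templates; the averaging
experiment uses 200-residue chains with 20 replicates per condition; the
enumeration oracle covers sequences up to length 6 over a reduced
alphabet (the exhaustive alignment count grows as the Delannoy numbers).
The pipeline is a pure function of (inputs, config, seed): run manifests
contain no timestamps, JSON is key-sorted, and reruns are byte-identical —
the determinism the acceptance script verifies.

## Known limitations

- Backbone-only models: no side chains, no loop closure, no refinement.
- Star-topology profiles understate column correlations a full MSA
  captures; profile-merging formulas are this package's own documented
  choices, not a reimplementation of any published server's internals.
- Identity weighting in averaging is a heuristic; restraint-based builders
  weight templates implicitly and can differ.
- The TM-score search is heuristic; on pathological geometries the
  fragment schedule could miss the global superposition (the test suite
  cross-checks an exhaustive-seed oracle on small cases).
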