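# Methods

This note documents the models, parameters and numerical choices behind
`intsymm`, and what the synthetic fixtures do and do not establish.

## Problem statement and assumptions

A chain has internal symmetry when an asymmetric structural unit occurs k
times in a regular arrangement: one rigid transform maps each repeat onto
the next. The method assumes rigid repeats (no flexible or conformationally
divergent copies), a sequential repeat layout (at most one circular
permutation, no shuffled repeat order), and a single operator per level
(superhelical arrangements, where the operator precesses, are outside the
model and at best approximated as `Hn`/`R`/`SH`). Quaternary symmetry is
out of scope; each chain is analyzed independently.

## Self-alignment

The similarity matrix compares fragments of window w = 8 by the mean
absolute difference of their intra-fragment Cα–Cα distances (a
superposition-free, rotation-invariant measure). Cells within a circular
sequence offset < w of the identity are masked, which excludes the identity
alignment and all near-identity paths. The path search is a local
affine-gap dynamic program (gap open 6.0, extend 0.6, in score units of Å
of fragment dissimilarity) over the trace versus a duplicated copy of
itself, so paths may wrap the C-terminus into the N-terminus; positions
mapped into the duplicate are reduced modulo n and the wrap marks a
circular permutation. Paths are oriented forward (each position maps to a
later one, modulo wrap) without loss of generality.

Two measures keep a path on a single symmetry operation:

* the fragment-similarity search runs once per candidate diagonal (local
  maxima of per-diagonal positive score mass), banded to ±2w, because an
  unconstrained path happily concatenates segments of the one-repeat and
  two-repeat diagonals — each locally perfect, jointly inconsistent with
  any rigid transform;
* each candidate mapping is then re-derived from superposition distances:
  given the mapping's best rigid transform T, cell (i, j) is scored by
  8 Å − |T(x_i) − x_j| and the path search repeats. Because this score is
  tied to one transform, operator mixing and fragment-window edge effects
  disappear. Two such iterations are run, keeping improvements only.

The highest-TM mapping wins; ties prefer longer alignments, then smaller
start positions. TM-score uses d0 = 1.24·(L−15)^(1/3) − 1.8 (floored at
0.5 Å) and the standard iterative superposition search (seeds on sliding
sub-windows of the pair list at three scales, re-fit on pairs within
max(d0+1, 3.5) Å until the selection is stable).

## Order detection

*DeltaPosition* evaluates δ_k = mean_i min(|f^k(i)−i|, n−|f^k(i)−i|) — the
circular distance, since closed symmetry wraps — over positions where the
k-fold composition is defined, and minimizes δ_k/n + α·k for k = 1..8.
α = 0.002 per unit k; its only role is to break exact ties (δ = 0 for every
multiple of the true period) toward the smallest exact period, and it is
small enough that any real displacement difference dominates. A result
k > 1 additionally requires δ_k/n below a ceiling of 0.1 and the
composition to be defined on at least 10% of the mapped positions.
*GraphComponent* takes the modal weakly-connected-component size in
[2, max_order] of the alignment graph, ties to the larger size; its
confidence is the fraction of nodes in modal components. *RotationAngle*
requires a transform rotation > 5° and matches it to 360/n within 10°.
Closed (circularly permuted) alignments use DeltaPosition, open ones
GraphComponent, overridable by the user.

## Refinement

Every size-k component (k-cycles for the DeltaPosition refiner, which first
deletes nodes with undefined k-fold composition and rewires walks whose
k-th step lands within 3 residues of the start) yields one candidate
ungapped column. Column selection maximizes alignment length by
longest-chain dynamic programming under elementwise dominance; a subsequent
greedy pass removes columns that make repeat ranges interleave (chain
dominance alone keeps every row increasing but cannot forbid repeat 1
reaching into repeat 2's range — a case that arises for adversarial graphs,
not for near-diagonal self-alignments). At least 3 columns are required,
otherwise refinement fails and the level is non-significant.

## Monte Carlo optimization

Score: S = Σ_ij [C/(1+(d_ij/d0)²) − A] − G·gaps with C = 20, d_c = 7 Å,
A = C/(1+(d_c/d0)²) (so a position scores exactly 0 at d_ij = d_c), and
G = C/2 — no published default exists for G; C/2 makes a gap preferable to
any cell scoring below −C/2. d_ij is the average distance from an aligned
residue to its column equivalents after the symmetry-constrained
superposition: a single consensus transform is fitted over all consecutive
row pairs and applied by powers, so equivalent positions keep the symmetric
orientation. Columns with fewer than two aligned cells score as gaps.

Moves (uniform kind weights; the schematic's per-edge probabilities are not
published): expand adds a column at a randomly chosen alignment end — rows
that cannot extend (chain terminus or neighbouring repeat) contribute a gap
cell, and the move is infeasible only when no row can extend, which is what
lets a truncated alignment grow back to full repeat length; shrink deletes
a column and insert-gap deletes a cell, both sampling ranks of the
distance-sorted candidates from a geometric distribution with p = 0.5
(worst first); shift slides a block of consecutive residues of one row by
±1. All moves preserve row monotonicity, disjointness and a ≥ 2-cell
minimum per row.

Acceptance of a worsening move: p = ((C+ΔS)/(C·m))·(1−m/M), clamped to
[0, 1] — proportional to the score difference and decreasing with the
iteration count m; the printed form of this schedule is typographically
ambiguous, and this reading satisfies both stated constraints. M defaults
to 100× the chain length; the run stalls out after M/50 consecutive
rejections. The best state visited is returned, so the output never scores
below the input. The penalization constant A is always derived from the
current chain's d0, including in recursion levels.

## Axes, types and point groups

The consensus transform is screw-decomposed (rotation eigen-axis, angle
from the rotation vector, translation split along/perpendicular to the
axis; the axis point is the minimum-norm least-squares solution of the
fixed-point equation). Closed levels are `Cn`. Open levels: |t| ≤ 2 Å or
θ ≤ 5° → `R` (the tolerances are this package's choice; "negligible" is
not quantified in the literature defaults), else `Hn` if θ is within 5° of
360/n for n ≤ 8, else `SH`.

Point groups: repeat centroids are rotated about the global centroid by a
deterministic super-Fibonacci quaternion grid (~16° resolution, about 3600
orientations); a candidate must permute centroids onto centroids within the
RMSD threshold (5 Å), is refined by a rotation-only Procrustes fit on all
Cα of fully aligned columns, and accepted below the same threshold. Valid
operations are closed under composition (newly generated permutations are
verified directly), and the group is classified from its axes: all parallel
→ Cn; an n-fold with n perpendicular 2-folds and group size 2n → Dn; sizes
12/24/60 → T/O/I.

Across recursion levels, collinear rotational axes (< 5° and < 2 Å apart)
multiply their orders; an orthogonal 2-fold against an n-fold gives `Dn`;
anything else is reported as a hierarchical list joined with "/".

## Engine and significance

Checkpoints: (1) self-alignment TM ≥ 0.4; (2) order > 1 and refinement
success; (3) average pairwise repeat TM ≥ 0.36 (a 10% relaxation of the
self-alignment threshold), computed as the mean TM over all repeat pairs,
each superimposed independently and normalized by the longer repeat's
length — repeats are the entities compared, so repeat length (not chain
length) is the normalization. A failed checkpoint 3 does not fall back to
the pre-optimization alignment; the level is non-significant. The
SSE gate on the final asymmetric repeating unit defaults to 0 so simple
repeat units (helical bundles) are included; secondary structure is
assigned from Cα geometry alone (helix: d(i,i+3) ∈ 5.3±0.6 Å and
d(i,i+4) ∈ 6.2±0.8 Å; strand: local d(i,i+2) ≥ 5.5 Å sustained; runs
shorter than 4 become coil), which is all the pipeline needs from an SSE
definition.

Determinism: one seed drives the Monte Carlo generator; identical inputs
and seeds give bit-identical results.

## Synthetic fixtures: what they are and are not

The generator arranges a seed motif by exact operator powers (cyclic,
dihedral, helical, translational, superhelical), joins repeats with linkers
replicated by the same operator, and adds optional iid Gaussian noise after
placement, so the operator remains the ground truth up to O(σ). The default
motif is an α/β unit (one helix + a β-hairpin, unequal arms). This choice
is substantive: idealized homogeneous motifs are themselves symmetric — two
α-helices always superimpose, and a single ideal helix is a perfect screw —
so hairpin or bare-helix motifs make the recursion *correctly* report
sub-repeat symmetry that the fixture's nominal truth does not anticipate.
An α/β unit has no internal self-match and is the realistic model of an
asymmetric repeating unit. Decoys are self-avoiding random Cα walks with
3.8 Å bonds and protein-like bond angles.

Fixture tests therefore establish algorithmic correctness under exact or
mildly noisy geometry with clean, globally consistent repeats. They do not
exercise conformational heterogeneity between repeats, large insertions,
multi-domain chains, kinked solenoids, or crystallographic artifacts — on
real structures the published behaviour of this method family (true
positives around three quarters of benchmark repeats, best performance on
closed single-domain repeats) is the realistic expectation, and nothing in
the fixture suite measures it.

Problem sizes used by the test suite: chains of ~50–260 residues (motifs
20–30 residues, 2–8 repeats), 40 generator seeds per cyclic order, 20 per
open arrangement, 20 decoys — chosen as the smallest set that separates
systematic failures from sampling noise at the 95% recovery bar.

## Known limitations

* No non-sequential repeat topologies beyond a single circular permutation,
  and no flexible alignment of diverged repeats.
* Superhelical paths are not fitted; `SH` is a residual label, not a model.
* The DeltaPosition displacement form and its repair heuristic implement
  the documented intent of the corrected detector (circular distances,
  small-offset cycle closure); the original's exact constants are not
  published, so behavioural equivalence is verified on fixtures, not
  claimed bit-for-bit.
* The optimizer's best score is monotone within a run by construction, but
  not formally monotone in the iteration budget M, because the acceptance
  schedule depends on M; in practice larger budgets help or tie.
* Cα-only secondary structure is a coarse heuristic adequate for counting
  elements, not a DSSP replacement.
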