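# Methods

This note documents the models, algorithms and numerical choices
behind `mrpilot`, in the spirit of a package methods section: what is
computed, under which assumptions, with which defaults, and what the
synthetic test bed does and does not demonstrate.

## Scope and architecture

`mrpilot` implements the *decision layer* of automated molecular
replacement: which model to try against which partial solution, when a
translation peak counts as a clear solution, how to prune the search
tree, and how to exploit relationships between solutions
(amalgamation, noncrystallographic assemblies, enantiomorph
arbitration). It deliberately does **not** implement diffraction
physics: the rotation/translation/packing/refinement/scoring
primitives are a backend interface, and the bundled backend is a
synthetic crystal with a geometry-based score. Any object providing
`rotation_search`, `translation_search`, `packing_check`,
`rigid_refine`, `score` and `background_zscore` with comparable scores
can replace it.

The controller state is a blackboard: a set of partial solutions per
active space group, updated by extension cycles. All results are
collected and processed in a canonical order (priority, then solution
id), so a run is reproducible bit-for-bit for a fixed seed regardless
of the worker count — a deliberate trade of scheduling realism for
testability.

## Crystallographic machinery

**Space groups.** Seven chiral groups are supported: P1, P2₁, C2,
P2₁2₁2₁, P2₁2₁2, P4₁ and P4₃. The set is small but spans every
symmetry situation the engine must handle: a fully polar triclinic
group, a polar monoclinic group, a centred lattice, nonpolar
orthorhombic groups, and a tetragonal enantiomorph pair. Operator
tables come from `gemmi`; polar axes are derived as the directions
fixed by every rotation part, and the discrete allowed origin shifts
are enumerated by conjugation: a shift **s** is allowed iff
(I − R)·s is a lattice translation for every operator rotation R,
deduplicated modulo lattice (including centring) translations and
polar directions. This reproduces the standard tables (8 shifts for
P2₁2₁2₁, {0, ½}² on a/c for P2₁, etc.) without hard-coding them.

**Rigid-body frames.** Symmetry operators act in the fractional
basis; placements and superposition live in orthogonal Ångströms,
connected by the PDB orthogonalization convention (`gemmi` cell
matrices). Kabsch superposition (SVD with determinant correction,
failure on <3 or collinear points) replaces secondary-structure
matching for all model-to-model superposition: all models of one
component share target-sequence numbering, so explicitly paired Cα
Kabsch is deterministic and sufficient, and needs no secondary
structure.

**Angle/axis decomposition.** The decomposition keeps the true
rotation sense, so `(θ, axis)` reconstructs the input rotation
exactly; the "first nonzero component positive" canonicalization is
applied only where the sign is genuinely free (θ = 0° or 180°).

**Spatial equivalence.** Two solutions are the same solution iff one
global catalogue operator plus one allowed origin move (discrete
shifts, plus a continuous component along polar axes anchored on a
candidate pairing) maps every placement of one onto a distinct
placement of the other within tolerances (defaults 5° / 2.0 Å).
Matching is a perfect matching on the feasibility matrix (Hungarian
algorithm). A subset variant supports output selection.

## Sequence bookkeeping

Coverage is tracked as 0-based half-open intervals on the target
sequence; alignment-derived coverage bridges internal gaps of ≤2
residues. Molecular weights use the Expasy average residue masses
plus one water; `X` counts 110.0 Da. The asymmetric-unit content is
chosen by the Matthews relation V_M = V_cell/(n_ops·Z·ΣMW·stoich)
with the standard protein solvent relation (solvent = 1 − 1.23/V_M),
scoring each copy number Z by a Gaussian plausibility on solvent
fraction centred at 0.50 with sd 0.12 — a coarse stand-in for the
empirical solvent distribution, adequate because the toy cells are
generated at known solvent. Both centre and sd are arguments.
Admissibility of a model against the missing composition allows a
coverage overlap of 10% of the model's covered length (configurable);
an underestimated composition simply ends the search at the requested
copy count (no recovery procedure is attempted).

## Model preparation

Models are Cα-only: every engine decision depends only on rigid-body
geometry and scattering weight, so side chains would change nothing;
the PDB reader extracts Cα from full-atom files. Template editing
offers a 6-protocol grid (pruning: none / unaligned /
unaligned-plus-low-identity; B factors: as-is / constant 20 /
20 + 60·(1 − window identity), with 9-residue windows and a 0.2
identity threshold — window size and B-factor mapping are this
package's choices, surfaced as module constants). Collections are
ensembled by iterative Kabsch superposition with trimming of residues
whose inter-member spread exceeds 2.5 Å. Priority follows input
specialization: ready ensembles, then collections, then
templates/hits (hits by descending identity); protocol variants of one
template are shuffled with the seeded generator, since there is no a
priori ranking among protocols.

## The synthetic crystal and the mock score

**Generation.** Components are compact self-avoiding Cα walks (bond
3.8 Å, minimum separation 3.4 Å) confined to a sphere at protein-like
density (~134 Å³/residue). The cell is sized from the total weight
and the target solvent fraction (default 0.5) through the Matthews
relation; cells are orthogonal, with a = b for tetragonal groups.
True placements are sampled by greedy insertion (each unit keeps the
least-overlapping of ~30 seeded poses) followed by rigid-body
relaxation: a soft-sphere overlap energy over all symmetry images is
minimized with L-BFGS using analytic forces and torques and a
periodic KD-tree neighbour search, with an annealed clearance
schedule. Assemblies (Cn/Dn) move as rigid units, so their orbits
remain exact; the ring radius is the smallest that keeps the assembly
internally clash-free. Truths are packed with a 2.0 Å clearance
margin beyond the 3.0 Å clash distance — the generator's own
tolerance — so that realistic models (coordinate noise ~0.8 Å) placed
on correct poses still pass the packing function.

**Score.** The LLG analogue of a solution is

    llg = max over allowed origin moves of
          Σ_p w_p · ov(p, matched truth)  − ½·w̄·n_clash  + noise

`ov` is an orbit overlap: the placement's images under the *solution*
space group are each compared against the best-matching image of the
matched truth under the *crystal* space group (mean per-residue
Gaussian, σ = 1.5 Å, lattice minimum image, exact zero beyond 6σ),
and averaged over the orbit. Matching of placements to truths is
greedy best-overlap without truth re-use. Consequences, all asserted
by tests: a placement exactly on a truth scores its full weight; the
score is invariant under one global operator plus an allowed origin
move and under per-placement *crystal-operator* images (which are the
same physical crystal), but not under independent generic moves; and
a wrong enantiomorph choice scores markedly lower because the
solution's own orbit no longer matches the crystal's — which is what
makes space-group arbitration decidable. Polar origin components are
optimized by candidate anchoring plus golden-section refinement
(0.01 Å tolerance). Score noise (sd ε·w_p, default ε = 0.02) is keyed
on discretized pose bins (1 Å / 5°) through a splitmix64 hash, so
identical poses rescore identically — determinism over realism.

**Searches.** The rotation function scores a super-Fibonacci SO(3)
grid (default step 15°) by orientation-only Gaussian overlap
(σ_rot = 10°) against unmatched truth image orientations, and
standardizes over the grid. The translation function evaluates the
overlap gain on a fractional grid (default step 2.0 Å) with the truth
matching of the parent held fixed; the TFZ analogue standardizes raw
over the whole grid, and local maxima (3³ wrap filter) are reported.
The clash penalty is *not* part of the landscape: packing is its own
workflow step, and folding clashes into the landscape would let the
occupied half of the cell dominate the grid statistics and destroy
the TFZ contrast. Reported peaks are interpolated to the sub-grid
rigid optimum (Powell, ±12° / ±1.5 grid steps) so that packing and
categorization judge the actual solution rather than its lattice
rounding; assembly predictions receive the same polish, since they
enter the workflow exactly like translation peaks. Rigid-body
refinement maximizes each placement's smooth score term (matched
overlap minus clashes) with Powell over 6 parameters, bounded to
±15° / ±5 Å, sweeping placements until the total improves by <1e-4.

**Background Z.** Non-search candidates (amalgamations, assembly
predictions) are judged by the Z of their overlap gain against ~200
seeded random placements of the same models. Clash terms are excluded
from both sides of this comparison: at 50% solvent, random poses
clash catastrophically and would inflate the background sd ~30-fold,
burying every genuine prediction; packing remains the separate
accept/reject filter.

## The search engine

Each extension cycle runs: composition analysis; evaluation of
pending predictions/amalgamations (each predicted placement is
polished, packed and Z-scored individually, so one spurious orbit
slot cannot veto the genuine ones; a clear prediction bypasses the
search for that lineage); rotation → translation → packing searches
in depth-first priority order (children of the best-scoring parent
first; translation searches walk the rotation list and stop at the
first clear peak); categorization (clear iff packs and TFZ ≥ 7.0);
percentage-threshold selection (f = 0.25 of the best score
improvement, clears retained); rigid-body refinement; a second
percentage threshold (clears again retained — the retention-through-
purge choice is logged); branch reduction by template equivalence
*before* the solution analyses (so the analyses see one
representative per equivalence class, not thirteen clones); then
amalgamation, assembly detection (tolerances 5°/5°/1.0 Å axial, order
≤ 12), NCS refresh, missing-member prediction capped by the missing
composition, optional composite assembly search models, and known-
assembly completion by a separable local grid search (±4 Å step 1 Å,
±10° step 5°). In quick mode, search scheduling stops once a clear
solution exists, alternative-model rescoring activates (same-template
alternatives scored without refinement, different-template ones
refined last-placement-only), and the run ends when a complete clear
solution exists. Full mode runs every (partial, model) search as an
independent job through the pooled executor.

All percentage fractions default to 0.25 and the clear threshold to
TFZ 7.0; these are configuration, not constants. The prediction
bypass uses the same 7.0 on the background Z. Predictions attached to
purged parents are dropped with their parent.

Output selection sorts by score, applies the percentage threshold,
and discards any solution whose placements match a subset of a
*better* solution under one global operator + origin move. "Better"
requires a margin above a score resolution of 0.01: differences below
that are numerical dust, and without the margin an over-placed
variant whose extra copy contributes nothing (or whose shared copies
merely re-refined by 1e-5) would displace the correct-count solution.
Equal scores rank the smaller solution first. Incomplete ancestors
are absorbed by the same rule, because their completion genuinely
scores higher.

Dry-run enumeration counts the unscored extension tree by recursion
over the remaining-copies state: with branch reduction off, the
number of complete assignments is the product of admissible-model
counts over extension steps; with template equivalence on, branches
collapse per template class while `evaluations` counts the model
evaluations the live reduced search still performs.

## What the synthetic tests do and do not show

The toy crystals emulate: realistic packing density (50% solvent),
crystallographic symmetry with origin/enantiomorph ambiguities, NCS
point-group assemblies, models with realistic coordinate error, and a
score obeying the maximum-likelihood comparability contract with
controllable peak-to-noise contrast. They do **not** emulate
resolution dependence, measurement error statistics, anisotropy,
solvent contribution, or the shape of real likelihood functions — so
passing tests certify the *decision logic* (what gets searched,
pruned, merged, predicted and reported), not phasing power on real
data. Score noise is deliberately pose-binned rather than stochastic
per call, and results are collected in canonical order; real
multi-CPU runs of an MR pipeline can take timing-dependent search
paths, a behaviour this package intentionally removes.

## Problem sizes used by the test suite

The bundled demonstrations are scaled for a single CPU: components of
16–24 residues, 1–20 copies, translation grids of 2–3 Å and rotation
grids of 15–25°. The headline assembly-completion case (four C5
pentamers, 20 copies, one monomer model, quick mode, 3 Å / 24° grids)
runs in a few minutes; the 13-model × 4-copy evaluation-count case
uses default grids and runs in well under a minute. Larger problems
change nothing structurally — every algorithm is polynomial in
placements × truths × operators — but the quadratic clash and overlap
kernels make molecule size the main cost driver.

## Known limitations

* Cα-only geometry; no side-chain or B-factor refinement.
* Seven space groups; no non-chiral or non-standard settings.
* The generator requires orthogonal cells (its KD-tree packer uses
  periodic boxes); the symmetry layer itself handles monoclinic
  angles.
* Assembly detection assumes point-group NCS; helical/translational
  NCS is out of scope.
* Amalgamation of siblings solved in frames differing by a symmetry
  *rotation* (not just an origin shift) relies on the score's
  per-placement image invariance; the candidate generator itself only
  enumerates origin shifts, as specified.
* The executor ships a local worker pool only; the job contract is
  pluggable but no batch-queue backend is provided.
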