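# Methods

This note documents the generative model behind tricgen, the choices made
where the design was genuinely open, and what the shipped tests do and do
not establish.

## Data model and internal representation

A dataset is a `(n_obs, n_feat, n_ctx)` grid. Internally every grid is a
single `float64` array: numeric datasets store values, symbolic datasets
store 0-based ranks into the alphabet's ordered symbol list, and `NaN`
encodes the MISSING sentinel. This keeps 10⁷–10⁸-cell datasets cheap
(8 bytes/cell) and makes rank distance — the symbolic metric used by
quality injection and order-preserving patterns — a plain subtraction.
Indices are 0-based everywhere, in (observation, feature, context) order,
and index sets are explicit sorted lists (no half-open ranges).

Non-order-preserving triclusters are stored compactly: a seed `c` plus one
factor per row/column/context (numeric), or a template seed matrix /
per-context seed matrices (symbolic). Any clean cell is reconstructed
exactly from this representation. Order-preserving triclusters store their
values explicitly together with the shared permutation, because the
seed+factor form cannot express an ordering constraint; materializing the
block is what guarantees the planted ordering is exact. The noise term
`η_ijk` of the coherence models is never a stored parameter: degradation is
applied post hoc by the quality injector, so the clean ground truth stays
recoverable from the tricluster specs alone.

## Background

Four families: uniform (continuous over `[min, max]` for real alphabets,
discrete over elements otherwise), normal, discrete (per-element
probabilities; symbolic/integer only), and missing (a null background).
Normal draws on bounded alphabets are clamped to the range — the source
material names the distribution but not a boundary rule; clamping is
deterministic and keeps the nominal center, at the cost of point masses at
the bounds (about 0.1% of cells for the Normal(0, 30) on [−100, 100] base
preset). Integer alphabets round to the nearest integer; symbolic alphabets
interpret mean/stdev in rank units and discretize the clamped sample.
A fully-missing background combined with nonzero background noise/error
percentages is rejected at validation: perturbing a MISSING cell is
undefined.

## Pattern synthesis

`validate_triple` is a pure total function implementing the admissibility
rules (order-preserving alone with two nones; constant combinable with
additive/multiplicative; additive and multiplicative mutually exclusive;
none only in order-preserving/constant triples; no arithmetic patterns on
symbolic data). Tests check it against an independent brute-force
evaluation of the rules over all 5³ = 125 triples (24 numeric, 10 symbolic
admissible).

Numeric synthesis samples the seed uniformly from the middle half of the
alphabet range (whole range when the middle half holds no integer), then
factors: additive factors uniform in `±range/(2·max dim)`, multiplicative
factors uniform in `[1, (bound/|c|)^{1/3}]` per patterned dimension, where
`bound` is the alphabet bound on the side of `c`'s sign. Multiplicative
factors are kept positive with magnitude ≥ 1 — the sign is carried by the
seed — because that makes in-range values constructive rather than
accidental: the block extremes are then monotone in the factor magnitudes.
In all cases the block min/max is evaluated directly and factor amplitudes
are halved until the block fits the alphabet; an alphabet too narrow for
any non-degenerate assignment (e.g. additive patterns on a binary
alphabet) collapses to the constant limit (all factors 0 or 1). Integer
alphabets round seeds and factors to integers.

Order-preserving blocks draw fiber values from the background distribution
restricted to the alphabet (uniform when the background is the missing
family), sort each fiber, and scatter it so that reading the ordered
dimension in `π` order is non-decreasing — ties are allowed; strict
increase is not required. The profile fixes `π` on the context dimension
(increasing → identity, decreasing → reversal, random → uniform
permutation); on rows/columns `π` is uniform.

## Structure and placement

Sizes are drawn per dimension from uniform or normal laws; normal draws are
rounded half-to-even (unbiased integerization) and clipped to `[1, dim]`.
A contiguous dimension (features or contexts) is a consecutive run with
start uniform on `[0, dim − len]`.

Placement is the one stage where the source principles needed an
algorithm. Triclusters are processed group by group in BFS order of the
group's interaction graph: the first member samples each index subset
independently; each later member picks an already-placed graph neighbour,
draws per-dimension shared counts (each ≥ 1, within the per-dimension caps,
product within the pairwise element quota `⌊O_elements · min(|T_a|,|T_b|)⌋`),
copies that sub-block of the partner's index sets and samples its remaining
indices outside the partner — so the pair shares exactly the drawn
count of cells. For a contiguous dimension the shared run sits at one end
of the partner's run and the new run extends outward. Candidates are
rejection-resampled whenever they touch a tricluster they are not
designated to overlap (incidental overlaps are forbidden so the solution
report labels overlap exactly) or exceed a quota against another group
member. The retry budget is 10,000 attempts per tricluster: in dense
packings (e.g. 120 triclusters in 10⁷ cells) the per-attempt success rate
of the last placements drops to ~2·10⁻³, which a 1,000-attempt budget fails
roughly one run in five. Infeasible requests degrade gracefully: the
maximal placed set is returned with a warning, and the CLI signals it with
exit code 2. The element quota is enforced pairwise, not on the union of a
tricluster's overlaps, matching the two-tricluster worked definition of the
quota.

Overlap groups: `⌊n · O_triclusters⌋` triclusters are marked overlapping
and split into groups of `k`; a remainder of one becomes a singleton (it
cannot overlap alone), a remainder of two or more forms a smaller final
group. Within a group the interaction graph is sampled uniformly over
connected labeled graphs for group sizes ≤ 5 (exhaustive enumeration);
larger groups use a random spanning tree plus independent extra edges,
which is connected but not exactly uniform. The realized graph is recorded
in the solution report.

## Plaid composition

Overlap cells are recomputed from the per-tricluster clean contributions in
generation order: sum, product, or average, with the base offset taken as 0
since each contribution already carries its own seed (a nonzero global
offset would double-count). Plaid `none` keeps the last-generated
tricluster's value. Composed values falling outside the alphabet are
clamped (and rounded first on integer alphabets): the dataset must remain
alphabet-valid, and clamping is the least surprising repair. Symbolic
datasets admit only the `none` plaid — sums of symbols are undefined.

## Quality injection

Order of application: triclusters (in id order), then background; within a
scope, missing, then noise, then errors, on disjoint cell sets — every
degraded cell gets exactly one label in the report. Overlap cells count as
tricluster cells, never background. Exact background counts use floor
(never exceeding the user's budget); tricluster counts are uniform integers
on `[0, ⌊|t| · pct⌋]`, drawn independently per category.

Noise replaces a value uniformly within the deviation band (`±N_dev`
intersected with the alphabet, excluding the original; rank distance for
symbolic data); an empty band leaves the value unchanged with a warning.
Tricluster-scope errors draw uniformly from the in-alphabet values at
distance strictly greater than `N_dev` — every such value qualifies,
including the alphabet minimum — falling back to the farther extreme when
the set is empty. Background-scope errors take the alphabet extreme farther
from the background distribution's expected value (midpoint for uniform,
mean for normal, probability-weighted mean for discrete), with ties broken
toward the maximum; note this can leave a cell unchanged when it already
sits at that extreme.

## Determinism

One `numpy` PCG64 generator, seeded once, is threaded through every stage
in a fixed order, and quality injection runs last — so a run with the same
seed and quality switched off reproduces the clean grid bit-identically,
which is how the tests separate planted structure from degradation. Floats
are serialized with `repr`, making output files byte-identical across runs
and exact on round-trip.

## What the generator does and does not emulate

The synthetic data reproduces the *structural* properties real three-way
data is believed to have — dimensions, value ranges, background
distributions, tricluster counts and size laws, overlap degree, missing/
noise/error rates (the `real/dataset*` presets encode published
characterizations of five datasets: yeast cell-cycle expression, stock
ratios, fMRI BOLD series, bibsonomy triples, Dutch temperatures). It does
not emulate spatial or temporal autocorrelation in the background,
heteroscedastic or structured (MNAR) missingness, lag-shifted temporal
patterns, or per-fiber distinct orderings. Passing tests therefore
establish correctness of the planted structure and its bookkeeping, not
that any algorithm's performance on these benchmarks transfers to a
particular real dataset.

The fMRI mimic preset uses feature count 494 (its two published
descriptions disagree, 464 vs 494). The bibsonomy mimic (`real/dataset4`,
7,000 triclusters with group size 3,000) and `scal/S2`/`scal/S3` are
configuration presets at the edge of or beyond what strict
no-incidental-overlap placement can realize; they parse and validate, and
generation degrades with placement warnings rather than failing.

## Problem sizes used in the shipped tests

Unit and property tests run on blocks of up to 5³ cells and datasets of
10³–10⁴ cells; the plaid and placement suites use 10³–10⁴-cell datasets
with 2–6 triclusters; the quality-bound suite repeats an 8-cell injection
1,000 times; the scalability smoke test generates the full 10⁷-cell
`scal/S1` preset (120 triclusters) in memory, a few seconds on one core.
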