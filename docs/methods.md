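# Methods

## Model

BHV space 𝒯_𝒩 is the union of Euclidean orthants ℝ₊^(2n−3), one per binary
topology on the leaf set 𝒩, glued along shared faces (topologies with
collapsed edges). It is CAT(0), so geodesics are unique and the squared
distance is convex on 𝒯_𝒩 × 𝒯_𝒩. A tree is represented here as a map from
splits (bipartitions of 𝒩, stored as bitmasks canonicalized to the block
not containing the lexicographically first leaf) to non-negative lengths;
zero-length edges are retained as boundary coordinates, never collapsed.

For ℒ ⊆ 𝒩, the restriction map Ψ_ℒ prunes leaves outside ℒ and merges the
resulting degree-2 vertices by summing lengths; on a fixed orthant it is
linear, with a 0/1 matrix whose (i, j) entry says that edge j of the
orthant projects onto edge i of the restricted tree. The extension space of
a binary tree T on ℒ is Ψ_ℒ⁻¹(T): inside each orthant of its connection
cluster it is the polytope {x ≥ 0 : M x = v_T}. Columns of zeros in M mark
*inconsequential* edges, free to take any length.

For a pair of trees the search runs over the product of their connection
clusters. Within one orthant pair, inconsequential lengths are pinned
(mutual restriction): a common edge inconsequential on one side copies the
other side's value, an edge inconsequential for both (or unshared and
inconsequential) is zero. This loses no minimizer and makes the feasible
set compact and convex, a product of scaled simplices — each constraint row
owns a disjoint group of variables because every column of the
block-diagonal reduced matrix contains exactly one 1.

## Geodesic engine

The proper support is found by the GTP refinement: for a support pair
(A, B), vertices are weighted |e|²/‖A‖² and |e|²/‖B‖², edges join
incompatible splits, and a minimum-weight vertex cover is computed as an
s–t min cut (a small hand-written Dinic max-flow with float capacities;
graphs here have at most ~n vertices per side, and the flow is called
inside the optimizer's innermost loop, so per-call overhead matters more
than asymptotics). If the cover weighs less than 1 − 1e−12 the pair splits
into (C_A, B∖C_B), (A∖C_A, C_B) and recursion continues.

Three boundary conventions:

* Uncommon splits of zero length ride along with weight 0; they never
  change cover weights or the length.
* A pair with no incompatibilities at all splits into (∅, B), (A, ∅):
  those edges shrink/grow independently through the shared orthant and
  contribute ‖A‖² + ‖B‖² — exactly what the leg formula gives for
  empty-sided legs.
* Common edges are not factored out beforehand: cross-subproblem split
  pairs are automatically compatible, so the incompatibility graph
  decomposes on its own and the refinement reaches the same support.

Path points: a common edge interpolates linearly; a dropped split e in leg
j survives with length ((1−λ)‖A_j‖ − λ‖B_j‖)·|e|₁/‖A_j‖ while that factor
is positive (a 1e−13 relative threshold absorbs cancellation noise exactly
at orthant crossings), and added splits mirror this from the other end.

## Optimizer

δ(ẋ) = d²(T1′(ẋ), T2′(ẋ)) is convex and C¹ on the interior of the
feasible polytope; each variable contributes to exactly one term of the
squared-length formula, so the gradient entry is 2ẋ(1 + ‖B_i‖/‖A_i‖) for a
dropped split in leg i, the mirror image for added splits, and 2(ẋ¹ − ẋ²)
for a common consequential edge (copied edges cancel identically and
contribute zero gradient).

Non-differentiability is confined to points where a support leg has a
zero-norm side. The masking is per side: an entry is undefined (reported
as 0, a subgradient choice) only when *its own* side's norm vanishes; a
zero opposite norm leaves the term smooth with ratio 0. Masking the whole
leg — both sides — makes steepest descent stall at perfectly smooth
points, which is why the finer rule is used.

The loop is a textbook reduced gradient method adapted to the unit-column
structure: the dependent variable of each constraint row acts as the row's
slack, the projected gradient is ∇φ_j = g_j − g_dep(row(j)) (the generic
dense form of the projection is also exposed and tested against this), the
descent direction is −∇φ on the free variables, and dependents are
re-solved from the constraints after every step to kill drift. Variables
hitting zero are reclassified as null (a dependent variable pivots its row
to the largest free variable first, keeping the basis a permutation
submatrix); rows whose target length is zero are frozen outright.

**Line search.** The 1-D restriction of δ is convex and C¹, so its
directional derivative is nondecreasing; the exact step is the derivative's
zero crossing, found by bisection to 1e−12·max(1, τ_max) and capped at the
non-negativity boundary. Bisection on the derivative rather than
golden-section on values is deliberate: value-based minimization cannot
localize a minimum better than ~√ε, which leaves gradient residuals of
order 1e−8 — precisely the convergence tolerance — at the next iterate.

**Certificate.** At a phase end the multipliers μ̄_j = g_j − g_dep(row(j))
are evaluated over the null variables. A negative formula value is
confirmed by a one-sided directional probe (step 1e−6 along "release j,
compensate through the row's dependent") before the variable is released:
at an orthant boundary, releasing a variable can create a brand-new
zero-norm support leg whose one-sided derivative is strictly positive even
though the zero-masked formula entry is negative; trusting the formula
there cycles forever between release and re-pinning. The probed slope is a
genuine subdifferential element and is what the certificate reports.

Defaults: gradient tolerance 1e−8, feasibility tolerance 1e−9 (absolute —
targets are sums of input lengths), 500 iterations per orthant pair
(observed: mean ≈ 4–7), initial point spreading each row target equally
over its variables (feasible and strictly positive wherever possible),
initial dependents the canonically first column of each row.

## Global search and supertrees

All Ω orthant pairs are optimized independently (optionally across a
process pool; the per-pair computation is a pure function and the reduction
is an associative min/merge, so results are order-independent). Ties within
relative 1e−6 of the minimum are collected; optimal pairs and midpoints are
deduplicated as trees after stripping internal edges below 1e−7. An
optional `stop_tol` ends the scan once a pair reaches that distance —
useful when probing for intersecting extension spaces, where zero is a
global lower bound, and exact in that case. The midpoint of each optimal
pair's geodesic is the reported supertree; the halving property
|d(T_i*, m) − d/2| ≤ 1e−6 is asserted in the test suite on every family of
instances the suite produces.

## Synthetic data

The generator emulates the simulation design the method was studied under:
uniform random binary topologies via sequential attachment (each of the
2m−3 edges equally likely, which makes all (2l−5)!! topologies
equiprobable), leaf-set presets (a)–(f) with size triples (7,6,4), (7,6,4),
(7,5,4), (10,9,8), (10,8,8), (10,8,7), and i.i.d. edge lengths from either
a lognormal with mean 5 and variance 1 or a 75/25 mixture of that with a
lognormal of mean 60 and variance 10. "Mean/variance" are read as moments
of the lognormal variable itself and back-solved to (μ, σ²) of the
underlying normal — the phrasing names the distribution's own mean; a
`parameterization="underlying"` switch provides the other reading. One
master seed drives leaf-subset choice, topologies, and lengths through
independent substreams.

What these fixtures do *not* emulate: phylogenetic estimation error,
correlation between topology and branch lengths, non-clock-like rate
variation, or any biological signal shared between the paired trees (the
two trees are sampled independently). Passing tests therefore demonstrate
algorithmic correctness on the stated distributions, not robustness to the
idiosyncrasies of real gene trees.

## Numerical choices and degenerate inputs

* Split canonicalization anchors to the lexicographically first leaf;
  ordering of edges (externals by leaf, then internals by their printed
  block) fixes every matrix layout deterministically.
* Tree equality in tests: absolute 1e−9 on lengths.
* Zero-length input edges are legal everywhere: uncommon zero splits are
  weightless in the support search; constraint rows with zero targets
  freeze their variables at zero.
* Rooted Newick inputs are unrooted by default (the two root-incident
  lengths merge); `keep_root` instead represents the root as a zero-length
  pseudo-leaf `__root__`, which embeds rooted problems in a space with one
  extra leaf.
* Missing branch lengths are a hard error unless a default is supplied —
  the metric is meaningless without lengths.

## Problem sizes used in the test suite

The suite exercises full searches at union sizes n ≤ 6 (up to a few
hundred orthant pairs per instance), geodesic oracle comparisons on 5-leaf
trees (exhaustive support enumeration), optimizer oracle comparisons on
systems with at most 4 free dimensions (nested-grid search over the
product-of-simplices polytope), and cluster enumerations up to the
2145-orthant case (7 leaves in a 10-leaf space). Larger settings — e.g.
the 418 275-pair preset (f) — are supported by the same code paths and
scale as Ω; they are exercised through the count/enumeration layer rather
than full optimization runs.

## Known limitations

* Runtime is dominated by Ω, which grows super-exponentially in the number
  of missing leaves; the method is practical when leaf sets overlap
  substantially. No orthant-pruning heuristics are implemented.
* The distance is not a metric (no positivity, no triangle inequality
  between extension spaces); interpret it as a dissimilarity.
* Input trees must be binary (connection clusters are defined for binary
  trees); multifurcating inputs are rejected rather than resolved.
* Fréchet means of more than two extension spaces are out of scope.
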