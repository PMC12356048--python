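# extspace

Shortest BHV distances between **extension spaces** of phylogenetic trees —
a dissimilarity for pairs of trees whose leaf sets differ, with midpoint
"supertrees".

## The problem

Distances in the Billera–Holmes–Vogtmann (BHV) tree space compare both the
topology and the branch lengths of two phylogenies, but only when the trees
share one leaf set 𝒩. In practice — gene trees across prokaryotes,
leave-n-out sensitivity analyses, trees estimated from different loci — leaf
sets overlap only partially. A tree T with leaves ℒ ⊂ 𝒩 still induces a
subset of the big space: its *extension space* E_T^𝒩, all trees on 𝒩 whose
restriction to ℒ (pruning the other leaves and merging the resulting
degree-2 vertices, summing lengths) equals T. This package computes

    d(E_{T1}^𝒩, E_{T2}^𝒩) = inf { d(t1, t2) : t1 ∈ E_{T1}^𝒩, t2 ∈ E_{T2}^𝒩 },

the shortest BHV distance between the two extension spaces, together with
the minimizing tree pairs and their geodesic midpoints, which average the
two phylogenies into candidate supertrees. Unlike neighborhood-based
compatibility measures, this quantity is defined for *any* two trees
(it is not a metric: distinct trees can have intersecting extension spaces
and hence zero distance).

## The algorithm

* **Geodesics.** The inner distance oracle is the geodesic treepath (GTP)
  support search: starting from the single-pair (cone path) support, each
  pair (A_i, B_i) of dropped/added splits is refined by solving a
  minimum-weight vertex cover on its bipartite incompatibility graph (an
  s–t min cut); the squared length is
  Σᵢ (‖A_i‖ + ‖B_i‖)² + Σ_{s∈K} (|s|₁ − |s|₂)².
* **Search region.** E_T^𝒩 meets finitely many maximal orthants — the
  *connection cluster*, enumerated by attaching the missing leaves to the
  tree's edges in every possible way, (2n−5)!!/(2l−5)!! orthants in total.
  Within an orthant pair, the candidate set is an affine slice
  Ṁẋ = v̇, ẋ ≥ 0 over the consequential edges, after pinning the
  inconsequential edge lengths (copied across trees for shared edges,
  zero otherwise); this mutually restricted polytope provably still
  contains a minimizing pair.
* **Optimization.** On each orthant pair the convex, piecewise-smooth
  objective δ(ẋ) = d²(T1′(ẋ), T2′(ẋ)) is minimized by a reduced gradient
  method: steepest descent in the free variables, exact line search on the
  convex one-dimensional restriction, reclassification of variables that
  hit zero, and a KKT-style certificate μ̄ over the pinned variables
  deciding global optimality of the subproblem.
* **Global answer.** The minimum over all Ω = {(2n−5)!!}²/((2l₁−5)!!(2l₂−5)!!)
  orthant pairs solves the problem; tied optimal pairs are deduplicated and
  their geodesic midpoints reported.

## Worked example

Two trees sharing only A, B, C (T1 also has D; T2 also has F, G):

```python
import extspace as es

t1 = es.parse_newick("((A:2,B:2):4,C:1,D:3);")
t2 = es.parse_newick("((A:1,B:1):3,(F:2,G:2):3,C:2);")
res = es.extension_distance(t1, t2)
```

prints (via the `demo` snippet in this README):

```
distance:            1.414214
orthant pairs:       245
optimal pairs:       1
iterations (mean):   4.57
T1*: (A:2,B:2,((C:1,D:3):1.00000000186,(F:2,G:2):3):2.99999999814);
T2*: (A:1,B:1,((C:1,D:3):1,(F:2,G:2):3):3);
supertree (midpoint): (A:1.5,B:1.5,((C:1,D:3):1.00000000093,(F:2,G:2):3):2.99999999907);
```

The search visited all 245 orthant pairs (35 orthants for the 4-leaf tree
× 7 for the 5-leaf tree in the 6-leaf union space). The optimal pair
extends each tree with the other's missing leaves so that only the A and B
external edges disagree (2 vs 1 each), giving d = √(1²+1²) = √2 ≈ 1.414214.
The midpoint supertree halves exactly that disagreement.

The same computation from a shell:

```
extspace dist t1.nwk t2.nwk --out report.json
extspace count --n 10 --l1 8 --l2 7          # prints 418275
extspace simulate --setting a --lengths bimodal --seed 7 --out-prefix pair
```

`simulate` reproduces the study conditions used throughout the tests:
six named size presets (a)–(f) for (|ℒ1∪ℒ2|, |ℒ1|, |ℒ2|), with edge lengths
drawn either from a lognormal with mean 5 and variance 1, or from a 75/25
mixture of that and a long-branch lognormal (mean 60, variance 10).

## Layout

| module | contents |
|---|---|
| `extspace.trees` | leaf sets, splits, trees, orthant topologies, Newick I/O |
| `extspace.geodesic` | GTP support search, geodesic lengths and path points |
| `extspace.extension` | TDR restriction, connection clusters, projection matrices, mutually restricted systems |
| `extspace.optimizer` | the per-orthant-pair reduced gradient method |
| `extspace.driver` | orthant-pair enumeration, global minimum, midpoints, counts |
| `extspace.synthgen` | random trees and scenario presets for simulation |
| `extspace.cli` | `extspace dist / count / simulate` |

See `docs/methods.md` for the model, numerical choices, and limitations.
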