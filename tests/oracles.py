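"""Independent oracles used by the test suite.

These deliberately avoid the package's algorithmic paths: the geodesic
oracle enumerates path-space supports exhaustively, the polytope oracle
searches the feasible set by nested grid refinement, and the topology
enumerator regenerates all binary topologies from scratch.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from extspace.trees import LeafSet, OrthantTopology, Split, Tree, _masks_compatible
from extspace.extension import ProjectionSystem
from extspace.optimizer import objective_delta


def brute_force_distance(t1: Tree, t2: Tree) -> float:
    """Geodesic length by exhaustive minimization of the support formula.

    Enumerates every ordered pair of partitions of the uncommon splits
    (parts may be empty on one side) satisfying the path-space validity
    condition (B_i compatible with A_j for i < j) and the nondecreasing
    ratio property, and minimizes the closed-form length.  Exponential;
    use only on <= 5-6 leaves.
    """
    full = t1.leaves.full_mask
    s1, s2 = set(t1.internal_splits), set(t2.internal_splits)
    C = s1 & s2
    A = sorted(s1 - C, key=Split.sort_key)
    B = sorted(s2 - C, key=Split.sort_key)
    common = sorted(C, key=Split.sort_key) + t1.external_splits
    base = sum((t1.lengths[s] - t2.lengths[s]) ** 2 for s in common)
    if not A and not B:
        return math.sqrt(base)

    def parts(items, k):
        for assign in itertools.product(range(k), repeat=len(items)):
            out = [[] for _ in range(k)]
            for it, a in zip(items, assign):
                out[a].append(it)
            yield out

    best = math.inf
    for k in range(1, len(A) + len(B) + 1):
        for pa in parts(A, k):
            for pb in parts(B, k):
                if any(not a and not b for a, b in zip(pa, pb)):
                    continue
                ok = True
                for i in range(k):
                    for j in range(i + 1, k):
                        for b in pb[i]:
                            for a in pa[j]:
                                if not _masks_compatible(a.mask, b.mask, full):
                                    ok = False
                if not ok:
                    continue
                norms = [
                    (
                        math.sqrt(sum(t1.lengths[x] ** 2 for x in a)),
                        math.sqrt(sum(t2.lengths[x] ** 2 for x in b)),
                    )
                    for a, b in zip(pa, pb)
                ]
                ratios = [math.inf if nb == 0 else na / nb for na, nb in norms]
                if any(ratios[i] > ratios[i + 1] + 1e-12 for i in range(k - 1)):
                    continue
                best = min(best, base + sum((na + nb) ** 2 for na, nb in norms))
    return math.sqrt(best)


def all_binary_topologies(leaves: LeafSet):
    """Every binary topology on ``leaves``, built by sequential attachment
    over label sets (no bitmask machinery shared with the package)."""
    labs = list(leaves.labels)

    def grow(edges, idx):
        # edges: list of frozensets (the block on the far side of the anchor)
        if idx == len(labs):
            yield edges
            return
        x = labs[idx]
        for p in list(edges):
            new = [frozenset([x]), p, p | {x}]
            for h in edges:
                if h == p:
                    continue
                new.append(h | {x} if p <= h else h)
            yield from grow(new, idx + 1)

    start = [frozenset([labs[1]]), frozenset([labs[2]]), frozenset([labs[1], labs[2]])]
    seen = set()
    for edges in grow(start, 3):
        internal = frozenset(
            frozenset(b) for b in edges if 2 <= len(b) <= len(labs) - 2
        )
        if internal in seen:
            continue
        seen.add(internal)
        yield OrthantTopology(leaves, [Split(leaves, sorted(b)) for b in internal])


def polytope_minimum(
    sys: ProjectionSystem, rounds: int = 8, grid: int = 7
) -> float:
    """Dense projected search of the feasible polytope by nested grids.

    The constraint rows partition the variables, so the feasible set is a
    product of scaled simplices; all but the first variable of each row
    are free coordinates, boxed and refined around the running best.
    Returns the minimal distance found.
    """
    rows = sys.row_of_var
    row_vars: dict[int, list[int]] = {}
    for j, r in enumerate(rows):
        row_vars.setdefault(int(r), []).append(j)
    multirows = [(r, js) for r, js in sorted(row_vars.items()) if len(js) > 1]
    free_dims = [(r, j) for r, js in multirows for j in js[1:]]

    x = np.zeros(sys.n_vars)
    for r, js in row_vars.items():
        if len(js) == 1:
            x[js[0]] = sys.v[r]

    def evaluate(vals):
        for (r, j), v in zip(free_dims, vals):
            x[j] = v
        for r, js in multirows:
            x[js[0]] = sys.v[r] - sum(x[j] for j in js[1:])
            if x[js[0]] < 0:
                return None
        return objective_delta(x, sys, check_feasible=False)

    if not free_dims:
        return math.sqrt(max(evaluate(()), 0.0))

    lo = np.zeros(len(free_dims))
    hi = np.array([sys.v[r] for r, _ in free_dims], dtype=float)
    cap = hi.copy()
    best = (math.inf, 0.5 * (lo + hi))
    for _ in range(rounds):
        axes = [np.linspace(a, b, grid) for a, b in zip(lo, hi)]
        for vals in itertools.product(*axes):
            f = evaluate(vals)
            if f is not None and f < best[0]:
                best = (f, np.array(vals))
        width = (hi - lo) * 0.25
        lo = np.maximum(best[1] - width, 0.0)
        hi = np.minimum(best[1] + width, cap)
    return math.sqrt(max(best[0], 0.0))
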