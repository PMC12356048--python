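"""Global orchestration: the distance between two extension spaces.

The shortest BHV distance between the extension spaces of two trees with
leaf sets inside a common union is found by enumerating every orthant pair
(one orthant from each tree's connection cluster), running the reduced
gradient method on each pair's mutually restricted system, and taking the
minimum over pairs.  Tied optimal pairs are collected and their geodesic
midpoints — candidate "supertrees" averaging the two phylogenies — are
returned deduplicated.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import Optional

from .extension import build_reduced_system, connection_cluster
from .geodesic import compute_geodesic, geodesic_point
from .optimizer import Options, PairResult, minimize_orthant_pair
from .trees import LeafSet, Tree

__all__ = ["count_orthant_pairs", "cluster_size", "extension_distance", "ExtensionDistanceResult"]

logger = logging.getLogger(__name__)


def _double_factorial(k: int) -> int:
    """k!! for odd k (1 for k <= 1), in exact integer arithmetic."""
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def cluster_size(n: int, l: int) -> int:
    """Number of maximal orthants in the extension space of a binary tree
    with ``l`` leaves inside the BHV space on ``n`` leaves: (2n-5)!!/(2l-5)!!."""
    if not 3 <= l <= n:
        raise ValueError("need 3 <= l <= n")
    return _double_factorial(2 * n - 5) // _double_factorial(2 * l - 5)


def count_orthant_pairs(n: int, l1: int, l2: int) -> int:
    """Omega = {(2n-5)!!}^2 / ((2l1-5)!! (2l2-5)!!), the number of orthant
    pairs the search visits."""
    return cluster_size(n, l1) * cluster_size(n, l2)


@dataclass
class ExtensionDistanceResult:
    """Outcome of the extension-space distance search."""

    distance: float
    optimal_pairs: list[tuple[Tree, Tree]]
    midpoints: list[Tree]
    n_orthant_pairs: int
    per_pair_stats: dict
    converged_all: bool

    @property
    def n_optimal_pairs(self) -> int:
        return len(self.optimal_pairs)


def _strip_zero_internal(tree: Tree, tol: float) -> Tree:
    keep = {s: w for s, w in tree.lengths.items() if s.is_external or w > tol}
    return Tree(tree.leaves, keep, validate=False)


def _pair_equal(a: tuple[Tree, Tree], b: tuple[Tree, Tree], tol: float) -> bool:
    return (
        _strip_zero_internal(a[0], tol).approx_equal(_strip_zero_internal(b[0], tol), tol)
        and _strip_zero_internal(a[1], tol).approx_equal(_strip_zero_internal(b[1], tol), tol)
    )


def _optimize_chunk(args) -> list[tuple[int, int, float, object]]:
    t1, t2, o1, cluster2, i1, opts = args
    out = []
    for i2, o2 in enumerate(cluster2):
        sys = build_reduced_system(t1, o1, t2, o2)
        res = minimize_orthant_pair(sys, opts)
        out.append((i1, i2, res.distance, res))
    return out


def extension_distance(
    t1: Tree,
    t2: Tree,
    N: Optional[LeafSet] = None,
    opts: Optional[Options] = None,
    threads: int = 1,
    stop_tol: Optional[float] = None,
    tie_rel_tol: float = 1e-6,
    tree_tol: float = 1e-7,
) -> ExtensionDistanceResult:
    """Shortest BHV distance between the extension spaces of ``t1``, ``t2``.

    ``N`` defaults to the union of the two leaf sets.  Every orthant pair
    is optimized independently (concurrently with ``threads > 1``); the
    global minimum, the tied optimal pairs (within relative ``tie_rel_tol``
    on the distance, deduplicated as trees with length tolerance
    ``tree_tol``), their geodesic midpoints, and per-pair iteration
    statistics are returned.  ``stop_tol`` optionally stops the scan once a
    pair reaches that distance (useful when probing for intersecting
    extension spaces, where 0 is a global lower bound).
    """
    if not t1.is_binary or not t2.is_binary:
        raise ValueError("input trees must be binary")
    opts = opts or Options()
    if N is None:
        N = LeafSet(set(t1.leaves.labels) | set(t2.leaves.labels))
    else:
        if not (t1.leaves.issubset(N) and t2.leaves.issubset(N)):
            raise ValueError("leaf sets must be contained in N")
    if len(N) < 4:
        raise ValueError("the union leaf set must have at least 4 leaves")

    cluster1 = list(connection_cluster(t1, N))
    cluster2 = list(connection_cluster(t2, N))
    omega = count_orthant_pairs(len(N), len(t1.leaves), len(t2.leaves))
    assert len(cluster1) * len(cluster2) == omega

    results: list[tuple[float, PairResult]] = []
    best = math.inf
    if threads > 1:
        tasks = [(t1, t2, o1, cluster2, i1, opts) for i1, o1 in enumerate(cluster1)]
        with ProcessPoolExecutor(max_workers=threads) as pool:
            for chunk in pool.map(_optimize_chunk, tasks):
                for _, _, dist, res in chunk:
                    results.append((dist, res))
                    best = min(best, dist)
                if stop_tol is not None and best <= stop_tol:
                    break
    else:
        done = False
        for o1 in cluster1:
            for o2 in cluster2:
                sys = build_reduced_system(t1, o1, t2, o2)
                res = minimize_orthant_pair(sys, opts)
                results.append((res.distance, res))
                best = min(best, res.distance)
                if len(results) % 1000 == 0:
                    logger.info(
                        "optimized %d/%d orthant pairs; best distance %.6g",
                        len(results), omega, best,
                    )
                logger.debug("pair %d: %s", len(results), res.to_dict())
                if stop_tol is not None and best <= stop_tol:
                    done = True
                    break
            if done:
                break

    tie_abs = max(best * tie_rel_tol, 1e-9)
    optimal: list[tuple[Tree, Tree]] = []
    for dist, res in results:
        if dist <= best + tie_abs:
            pair = res.trees
            if not any(_pair_equal(pair, q, tree_tol) for q in optimal):
                optimal.append(pair)

    midpoints: list[Tree] = []
    for a, b in optimal:
        m = geodesic_point(compute_geodesic(a, b), 0.5)
        ms = _strip_zero_internal(m, tree_tol)
        if not any(ms.approx_equal(_strip_zero_internal(q, tree_tol), tree_tol) for q in midpoints):
            midpoints.append(m)

    iters = [res.iterations for _, res in results]
    stats = {
        "pairs_optimized": len(results),
        "iterations_mean": sum(iters) / len(iters) if iters else 0.0,
        "iterations_max": max(iters, default=0),
        "n_not_converged": sum(1 for _, r in results if not r.converged),
    }
    return ExtensionDistanceResult(
        distance=best,
        optimal_pairs=optimal,
        midpoints=midpoints,
        n_orthant_pairs=omega,
        per_pair_stats=stats,
        converged_all=stats["n_not_converged"] == 0,
    )
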