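"""BHV geodesic engine: the geodesic treepath (GTP) support search.

The geodesic between two trees on the same leaf set is characterized by its
*proper support*: ordered partitions (A_1..A_k) of the internal splits
dropped from the first tree and (B_1..B_k) of those added toward the second
tree, with common edges (internal splits shared by both trees, plus all
external edges) interpolating linearly.  The squared geodesic length is

    d^2 = sum_i (||A_i|| + ||B_i||)^2 + sum_{s common} (|s|_1 - |s|_2)^2,

where ``||P||`` is the Euclidean norm of the edge lengths of P.  Starting
from the single-pair (cone path) support, the proper support is found by
repeatedly solving the *extension problem* on each pair: build the bipartite
incompatibility graph between A_i and B_i with vertices weighted by squared
relative lengths, find a minimum-weight vertex cover (an s-t min cut), and
split the pair whenever the cover weighs less than one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .trees import Split, Tree, _masks_compatible

__all__ = ["GeodesicSupport", "Geodesic", "compute_geodesic", "geodesic_point", "distance"]

#: tolerance on the min-cover weight comparison against 1 (orthant boundary)
COVER_EPS = 1e-12


# ---------------------------------------------------------------------------
# Minimum-weight vertex cover on a bipartite graph, via max-flow (Dinic)
# ---------------------------------------------------------------------------

def min_weight_vertex_cover(
    wa: Sequence[float], wb: Sequence[float], edges: Sequence[tuple[int, int]]
) -> tuple[float, list[int], list[int]]:
    """Minimum-weight vertex cover of a bipartite graph.

    Vertices ``0..len(wa)-1`` on the A side (weights ``wa``) and
    ``0..len(wb)-1`` on the B side; ``edges`` are (a, b) index pairs.  By
    LP duality the cover weight equals the max flow in the network
    source->a (cap wa), b->sink (cap wb), a->b (cap inf), and the cover is
    read off the residual min cut.

    Returns ``(weight, cover_a, cover_b)``.
    """
    na, nb = len(wa), len(wb)
    n_nodes = na + nb + 2
    src, snk = na + nb, na + nb + 1
    inf = sum(wa) + sum(wb) + 1.0

    # adjacency: list of edge ids per node; edges stored as [to, cap]; the
    # reverse edge of edge e is e ^ 1
    graph: list[list[int]] = [[] for _ in range(n_nodes)]
    e_to: list[int] = []
    e_cap: list[float] = []

    def add_edge(u: int, v: int, cap: float) -> None:
        graph[u].append(len(e_to))
        e_to.append(v)
        e_cap.append(cap)
        graph[v].append(len(e_to))
        e_to.append(u)
        e_cap.append(0.0)

    for i, w in enumerate(wa):
        add_edge(src, i, float(w))
    for j, w in enumerate(wb):
        add_edge(na + j, snk, float(w))
    for a, b in edges:
        add_edge(a, na + b, inf)

    eps = 1e-15
    flow = 0.0
    while True:
        # BFS level graph
        level = [-1] * n_nodes
        level[src] = 0
        queue = [src]
        for u in queue:
            for eid in graph[u]:
                v = e_to[eid]
                if e_cap[eid] > eps and level[v] < 0:
                    level[v] = level[u] + 1
                    queue.append(v)
        if level[snk] < 0:
            break
        it = [0] * n_nodes

        def dfs(u: int, pushed: float) -> float:
            if u == snk:
                return pushed
            while it[u] < len(graph[u]):
                eid = graph[u][it[u]]
                v = e_to[eid]
                if e_cap[eid] > eps and level[v] == level[u] + 1:
                    got = dfs(v, min(pushed, e_cap[eid]))
                    if got > eps:
                        e_cap[eid] -= got
                        e_cap[eid ^ 1] += got
                        return got
                it[u] += 1
            return 0.0

        while True:
            pushed = dfs(src, inf)
            if pushed <= eps:
                break
            flow += pushed

    # residual reachability from the source
    seen = [False] * n_nodes
    seen[src] = True
    queue = [src]
    for u in queue:
        for eid in graph[u]:
            v = e_to[eid]
            if e_cap[eid] > eps and not seen[v]:
                seen[v] = True
                queue.append(v)
    cover_a = [i for i in range(na) if not seen[i]]
    cover_b = [j for j in range(nb) if seen[na + j]]
    return flow, cover_a, cover_b


# ---------------------------------------------------------------------------
# Support search
# ---------------------------------------------------------------------------

@dataclass
class GeodesicSupport:
    """The proper support of a geodesic plus its common-edge set.

    ``a_sets[i]``/``b_sets[i]`` are the splits dropped from / added toward
    the endpoint trees in leg ``i`` (sorted canonically); ``common`` holds
    the shared internal splits and all external edges.  A leg may have an
    empty side when the remaining uncommon splits of the two trees are
    mutually compatible (they then shrink/grow independently).
    """

    a_sets: list[list[Split]]
    b_sets: list[list[Split]]
    common: list[Split]
    a_norms: list[float]
    b_norms: list[float]

    def ratios(self) -> list[float]:
        """||A_i||/||B_i|| per leg (inf for empty B); 0/0 legs omitted."""
        out = []
        for a, b in zip(self.a_norms, self.b_norms):
            if a == 0.0 and b == 0.0:
                continue
            out.append(math.inf if b == 0.0 else a / b)
        return out


@dataclass
class Geodesic:
    source: Tree
    target: Tree
    support: GeodesicSupport
    length: float

    def point(self, lam: float) -> Tree:
        return geodesic_point(self, lam)

    def to_dict(self) -> dict:
        """JSON-serializable report: support as split strings, norms, length."""
        sup = self.support
        return {
            "length": self.length,
            "A_sets": [[str(s) for s in a] for a in sup.a_sets],
            "B_sets": [[str(s) for s in b] for b in sup.b_sets],
            "A_norms": list(sup.a_norms),
            "B_norms": list(sup.b_norms),
            "common": [str(s) for s in sup.common],
        }


def _norm(tree: Tree, splits: Sequence[Split]) -> float:
    return math.sqrt(sum(tree.lengths[s] ** 2 for s in splits))


def _refine(t1: Tree, t2: Tree, A: list[Split], B: list[Split]) -> list[tuple[list[Split], list[Split]]]:
    """Recursive extension-problem refinement of one support pair."""
    if not A or not B:
        return [(A, B)]
    na2 = sum(t1.lengths[a] ** 2 for a in A)
    nb2 = sum(t2.lengths[b] ** 2 for b in B)
    if na2 == 0.0 or nb2 == 0.0:
        return [(A, B)]  # degenerate leg: contributes ||A||^2 + ||B||^2 either way

    full = t1.leaves.full_mask
    edges = [
        (i, j)
        for i, a in enumerate(A)
        for j, b in enumerate(B)
        if not _masks_compatible(a.mask, b.mask, full)
    ]
    if not edges:
        # fully compatible: drop A and grow B through the combined orthant
        return [([], B), (A, [])]

    wa = [t1.lengths[a] ** 2 / na2 for a in A]
    wb = [t2.lengths[b] ** 2 / nb2 for b in B]
    weight, ca, cb = min_weight_vertex_cover(wa, wb, edges)
    if weight >= 1.0 - COVER_EPS:
        return [(A, B)]
    ca_set, cb_set = set(ca), set(cb)
    A1 = [A[i] for i in range(len(A)) if i in ca_set]
    B1 = [B[j] for j in range(len(B)) if j not in cb_set]
    A2 = [A[i] for i in range(len(A)) if i not in ca_set]
    B2 = [B[j] for j in range(len(B)) if j in cb_set]
    return _refine(t1, t2, A1, B1) + _refine(t1, t2, A2, B2)


def compute_geodesic(t1: Tree, t2: Tree) -> Geodesic:
    """The unique BHV geodesic between two trees on the same leaf set."""
    if t1.leaves != t2.leaves:
        raise ValueError("trees must share the same leaf set")

    s1 = set(t1.internal_splits)
    s2 = set(t2.internal_splits)
    common_internal = s1 & s2
    A0 = sorted(s1 - common_internal, key=Split.sort_key)
    B0 = sorted(s2 - common_internal, key=Split.sort_key)

    pairs = _refine(t1, t2, A0, B0) if (A0 or B0) else []
    pairs = [(a, b) for a, b in pairs if a or b]

    common = sorted(common_internal, key=Split.sort_key) + t1.external_splits
    a_sets = [sorted(a, key=Split.sort_key) for a, _ in pairs]
    b_sets = [sorted(b, key=Split.sort_key) for _, b in pairs]
    a_norms = [_norm(t1, a) for a in a_sets]
    b_norms = [_norm(t2, b) for b in b_sets]

    sq = sum((na + nb) ** 2 for na, nb in zip(a_norms, b_norms))
    sq += sum((t1.lengths[s] - t2.lengths.get(s, 0.0)) ** 2 for s in common)
    support = GeodesicSupport(a_sets, b_sets, common, a_norms, b_norms)
    return Geodesic(t1, t2, support, math.sqrt(sq))


def distance(t1: Tree, t2: Tree) -> float:
    """BHV distance (geodesic length) between two trees on one leaf set."""
    return compute_geodesic(t1, t2).length


def geodesic_point(g: Geodesic, lam: float) -> Tree:
    """The tree at parameter ``lam`` in [0, 1] along a geodesic.

    Common edges interpolate linearly; a dropped split ``e`` in leg ``j``
    survives with length ``((1-lam)||A_j|| - lam||B_j||) |e|_1 / ||A_j||``
    while positive, and added splits mirror this from the other end.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    t1, t2 = g.source, g.target
    sup = g.support
    lengths: dict[Split, float] = {}
    for s in sup.common:
        v = (1.0 - lam) * t1.lengths[s] + lam * t2.lengths.get(s, 0.0)
        lengths[s] = v
    for a_set, b_set, na, nb in zip(sup.a_sets, sup.b_sets, sup.a_norms, sup.b_norms):
        # strictly-positive threshold absorbs cancellation noise at the
        # exact orthant-boundary crossing
        eps = 1e-13 * (na + nb)
        if na > 0.0:
            coeff = ((1.0 - lam) * na - lam * nb) / na
            if coeff * na > eps:
                for e in a_set:
                    w = coeff * t1.lengths[e]
                    if w > 0.0:
                        lengths[e] = w
        if nb > 0.0:
            coeff = (lam * nb - (1.0 - lam) * na) / nb
            if coeff * nb > eps:
                for e in b_set:
                    w = coeff * t2.lengths[e]
                    if w > 0.0:
                        lengths[e] = w
    return Tree(t1.leaves, lengths)
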