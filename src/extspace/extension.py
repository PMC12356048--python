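"""Extension-space machinery.

A tree ``T`` on a leaf set ``L`` contained in a larger set ``N`` induces an
*extension space* in the BHV space on ``N``: all trees on ``N`` whose
restriction to ``L`` (under the tree dimensionality reduction map) equals
``T``.  The extension space is a finite union of affine slices, one per
maximal orthant in the *connection cluster* of ``T`` — the orthants obtained
by attaching the missing leaves of ``N \\ L`` to the edges of ``T`` in every
possible way.  Within one orthant the slice is the solution set of a 0/1
linear system ``M x = v_T`` whose matrix records which edge of the big
orthant projects onto which edge of ``T``; columns of zeros mark
*inconsequential* edges whose length the restriction does not see.

For a pair of trees, the *mutually restricted* system pins those
inconsequential lengths (copied from the other tree when the edge is common,
zero otherwise), leaving a block-diagonal constraint system over the
consequential edges only.  Minimizing the BHV distance over that system is
the optimizer module's job.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .trees import LeafSet, OrthantTopology, Split, Tree

__all__ = [
    "project_split",
    "tdr_project",
    "connection_cluster",
    "projection_matrix",
    "build_reduced_system",
    "reconstruct_pair",
    "ProjectionMatrix",
    "ProjectionSystem",
]


def project_split(s: Split, L: LeafSet) -> Optional[Split]:
    """Restrict a split on a big leaf set to the sub-leaf set ``L``.

    Returns the split separating ``L``'s leaves on either side of ``s``, or
    ``None`` when all of ``L`` falls on one side (the edge vanishes under
    restriction).  The result may be an external split of ``L`` even if
    ``s`` is internal.
    """
    if not L.issubset(s.universe):
        raise ValueError("L is not a subset of the split's universe")
    side = set(s.universe.labels_of(s.mask))
    inside = [lab for lab in L.labels if lab in side]
    if not inside or len(inside) == len(L):
        return None
    return Split(L, inside)


def tdr_project(t: Tree, L: LeafSet) -> Tree:
    """The tree dimensionality reduction map: restrict ``t`` to ``L``.

    Edges outside every leaf-to-leaf path within ``L`` are removed, and
    chains through the resulting degree-2 vertices are merged by summing
    lengths; equivalently, each edge of the restricted tree gets the sum of
    the lengths of the big-tree edges projecting onto it (the map is linear
    on length vectors).
    """
    if len(L) < 3:
        raise ValueError("need at least 3 leaves to project onto")
    if not L.issubset(t.leaves):
        raise ValueError("L is not a subset of the tree's leaves")
    if L == t.leaves:
        return Tree(t.leaves, dict(t.lengths), validate=False)
    acc: dict[Split, float] = {}
    for s, w in t.lengths.items():
        q = project_split(s, L)
        if q is not None:
            acc[q] = acc.get(q, 0.0) + w
    return Tree(L, acc)


# ---------------------------------------------------------------------------
# Connection clusters
# ---------------------------------------------------------------------------

def connection_cluster(t: Tree, N: LeafSet) -> Iterator[OrthantTopology]:
    """Enumerate the maximal orthants of the extension space of ``t`` in ``N``.

    Missing leaves are attached sequentially in a fixed lexicographic
    order; with a fixed order the attachment sequences biject onto the
    distinct topologies, so each of the (2n-5)!!/(2l-5)!! orthants is
    yielded exactly once with no deduplication pass.
    """
    if not t.is_binary:
        raise ValueError("connection clusters are defined for binary trees")
    if not t.leaves.issubset(N):
        raise ValueError("tree leaves must be contained in N")
    if len(t.leaves) < 3:
        raise ValueError("need at least 3 leaves")

    missing = sorted(set(N.labels) - set(t.leaves.labels))
    anchor_bit = 1 << N.index[t.leaves.labels[0]]
    n = len(N)

    # edges of the current (growing) tree as blocks over N not containing
    # the anchor: singleton blocks for non-anchor leaves, the co-anchor
    # block for the anchor's edge, and one block per internal split
    blocks: list[int] = []
    lmask = N.mask_of(t.leaves.labels)
    for lab in t.leaves.labels:
        bit = 1 << N.index[lab]
        blocks.append(lmask & ~anchor_bit if bit == anchor_bit else bit)
    for s in t.internal_splits:
        m = N.mask_of(s.universe.labels_of(s.mask))
        if m & anchor_bit:
            m = lmask & ~m
        blocks.append(m)
    blocks.sort()

    def attach(blocks: list[int], idx: int) -> Iterator[list[int]]:
        if idx == len(missing):
            yield blocks
            return
        x_bit = 1 << N.index[missing[idx]]
        for p in blocks:
            new_blocks = [x_bit, p, p | x_bit]
            for h in blocks:
                if h == p:
                    continue
                new_blocks.append(h | x_bit if (p & ~h) == 0 else h)
            new_blocks.sort()
            yield from attach(new_blocks, idx + 1)

    for final in attach(blocks, 0):
        internal = [
            Split(N, m) for m in final if 2 <= m.bit_count() <= n - 2
        ]
        yield OrthantTopology(N, internal, validate=False)


# ---------------------------------------------------------------------------
# Projection matrices and reduced systems
# ---------------------------------------------------------------------------

@dataclass
class ProjectionMatrix:
    """The 0/1 incidence of the TDR map on one orthant of the big space.

    Rows are the ``2l-3`` edges of ``t`` (externals in leaf order, then
    internals); columns the ``2n-3`` edges of the orthant ``O``; entry
    ``[i, j] = 1`` iff edge ``j`` of ``O`` projects onto edge ``i`` of
    ``t``.  Zero columns are the inconsequential edges.
    """

    rows: list[Split]
    cols: list[Split]
    matrix: np.ndarray
    consequential: list[bool]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def reduced(self) -> np.ndarray:
        """The matrix restricted to consequential columns."""
        keep = [j for j, c in enumerate(self.consequential) if c]
        return self.matrix[:, keep]


def projection_matrix(t: Tree, O: OrthantTopology) -> ProjectionMatrix:
    """Build the TDR incidence matrix of orthant ``O`` over tree ``t``.

    Raises if ``O`` is not in the connection cluster of ``t`` (some edge of
    ``t`` would have an empty preimage).
    """
    rows = t.all_splits
    cols = O.all_splits
    row_index = {s: i for i, s in enumerate(rows)}
    mat = np.zeros((len(rows), len(cols)), dtype=np.int8)
    consequential = []
    for j, p in enumerate(cols):
        q = project_split(p, t.leaves)
        if q is None:
            consequential.append(False)
            continue
        i = row_index.get(q)
        if i is None:
            raise ValueError(
                f"orthant is not in the connection cluster: column {p} "
                f"projects to {q}, not an edge of the tree"
            )
        mat[i, j] = 1
        consequential.append(True)
    if not (mat.sum(axis=1) > 0).all():
        raise ValueError("orthant is not in the connection cluster: empty preimage row")
    return ProjectionMatrix(rows, cols, mat, consequential)


@dataclass
class ProjectionSystem:
    """The mutually restricted linear system of one orthant pair.

    Variables are the consequential edges of the two orthants (tree 1's
    first, each group externals-then-internals); ``M`` is the
    block-diagonal constraint matrix, ``v`` the stacked edge-length vectors
    of the two input trees.  ``copy_rules`` pin common edges that are
    inconsequential on exactly one side to the other side's value;
    ``zero_rules`` pin the remaining inconsequential edges to zero.  Every
    edge of either orthant is covered by exactly one variable, copy rule,
    or zero rule.
    """

    orthants: tuple[OrthantTopology, OrthantTopology]
    trees: tuple[Tree, Tree]
    m1: ProjectionMatrix
    m2: ProjectionMatrix
    M: np.ndarray
    v: np.ndarray
    variables: list[tuple[int, Split]]
    var_index: dict[tuple[int, Split], int]
    copy_rules: list[tuple[Split, int, int]]  # (split, from_tree, to_tree)
    zero_rules: list[tuple[Split, int]]
    feas_tol: float = 1e-9

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    @property
    def row_of_var(self) -> np.ndarray:
        """Row index of each variable's single 1 (columns are unit vectors)."""
        return np.argmax(self.M, axis=0)

    def initial_point(self) -> np.ndarray:
        """Spread each row's target equally over its variables (feasible,
        strictly positive wherever the row target is positive)."""
        rows = self.row_of_var
        counts = np.bincount(rows, minlength=self.M.shape[0])
        return self.v[rows] / counts[rows]

    def is_feasible(self, x: np.ndarray, tol: Optional[float] = None) -> bool:
        tol = self.feas_tol if tol is None else tol
        return bool((x >= -tol).all() and np.abs(self.M @ x - self.v).max() <= tol)

    def to_debug_dict(self) -> dict:
        return {
            "variables": [f"T{j}:{s}" for j, s in self.variables],
            "M1_reduced": ["".join(str(int(e)) for e in row) for row in self.m1.reduced()],
            "M2_reduced": ["".join(str(int(e)) for e in row) for row in self.m2.reduced()],
            "v": list(map(float, self.v)),
            "copy_rules": [f"{s}: T{a}->T{b}" for s, a, b in self.copy_rules],
            "zero_rules": [f"{s}: T{j}" for s, j in self.zero_rules],
        }


def build_reduced_system(
    t1: Tree, O1: OrthantTopology, t2: Tree, O2: OrthantTopology
) -> ProjectionSystem:
    """Assemble the mutually restricted system for one orthant pair."""
    if O1.leaves != O2.leaves:
        raise ValueError("orthants live in different BHV spaces")
    pm1 = projection_matrix(t1, O1)
    pm2 = projection_matrix(t2, O2)

    cons1 = {s: c for s, c in zip(pm1.cols, pm1.consequential)}
    cons2 = {s: c for s, c in zip(pm2.cols, pm2.consequential)}
    p1, p2 = set(pm1.cols), set(pm2.cols)

    variables: list[tuple[int, Split]] = []
    variables += [(1, s) for s in pm1.cols if cons1[s]]
    variables += [(2, s) for s in pm2.cols if cons2[s]]
    var_index = {key: i for i, key in enumerate(variables)}

    copy_rules: list[tuple[Split, int, int]] = []
    zero_rules: list[tuple[Split, int]] = []
    for s in sorted(p1 | p2, key=Split.sort_key):
        in1, in2 = s in p1, s in p2
        if in1 and in2:
            c1, c2 = cons1[s], cons2[s]
            if c1 and not c2:
                copy_rules.append((s, 1, 2))
            elif c2 and not c1:
                copy_rules.append((s, 2, 1))
            elif not c1 and not c2:
                zero_rules.append((s, 1))
                zero_rules.append((s, 2))
        elif in1 and not cons1[s]:
            zero_rules.append((s, 1))
        elif in2 and not cons2[s]:
            zero_rules.append((s, 2))

    r1 = pm1.reduced()
    r2 = pm2.reduced()
    M = np.zeros((r1.shape[0] + r2.shape[0], r1.shape[1] + r2.shape[1]))
    M[: r1.shape[0], : r1.shape[1]] = r1
    M[r1.shape[0]:, r1.shape[1]:] = r2
    v = np.array(t1.edge_vector() + t2.edge_vector(), dtype=float)

    return ProjectionSystem(
        orthants=(O1, O2),
        trees=(t1, t2),
        m1=pm1,
        m2=pm2,
        M=M,
        v=v,
        variables=variables,
        var_index=var_index,
        copy_rules=copy_rules,
        zero_rules=zero_rules,
    )


def reconstruct_pair(
    x: Sequence[float], sys: ProjectionSystem, check: bool = True
) -> tuple[Tree, Tree]:
    """Map a feasible variable vector to its unique tree pair.

    Applies the variable assignments, then the copy and zero rules; the
    returned trees carry the full topologies of their orthants (possibly
    with zero-length edges) and lie in the orthant-specific mutually
    restricted extension space.
    """
    x = np.asarray(x, dtype=float)
    if check and not sys.is_feasible(x):
        raise ValueError("infeasible variable vector")
    O1, O2 = sys.orthants
    lengths: tuple[dict, dict] = ({}, {})
    for (j, s), xi in zip(sys.variables, x):
        lengths[j - 1][s] = max(float(xi), 0.0)
    for s, src, dst in sys.copy_rules:
        lengths[dst - 1][s] = lengths[src - 1][s]
    for s, j in sys.zero_rules:
        lengths[j - 1][s] = 0.0
    return O1.tree(lengths[0]), O2.tree(lengths[1])
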