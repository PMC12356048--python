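"""Tree and split data model.

A phylogenetic tree on a leaf set ``L`` is represented as a map from splits
(bipartitions of ``L``) to non-negative branch lengths.  Every edge of an
unrooted tree is identified by the bipartition it induces when removed, so a
split is the universal edge identity across trees and topology orthants in
BHV space.  Splits are stored as bitmasks over a deterministically
(lexicographically) ordered leaf set, canonicalized to the block that does
not contain the first leaf, so split equality and hashing are cheap and
independent of input order.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Mapping, Optional

__all__ = [
    "LeafSet",
    "Split",
    "Tree",
    "OrthantTopology",
    "parse_newick",
    "write_newick",
    "splits_compatible",
    "is_valid_topology",
]

ROOT_PSEUDO_LEAF = "__root__"


class LeafSet:
    """An ordered collection of distinct leaf names.

    Labels are sorted lexicographically regardless of input order, so that
    bit ``i`` of a split mask always refers to the same leaf.
    """

    __slots__ = ("labels", "index", "full_mask")

    def __init__(self, labels: Iterable[str]):
        labs = tuple(sorted(labels))
        if len(labs) != len(set(labs)):
            raise ValueError("duplicate leaf labels")
        if not labs or any((not isinstance(x, str)) or x == "" for x in labs):
            raise ValueError("leaf labels must be non-empty strings")
        self.labels = labs
        self.index = {name: i for i, name in enumerate(labs)}
        self.full_mask = (1 << len(labs)) - 1

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.index

    def __eq__(self, other) -> bool:
        return isinstance(other, LeafSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"LeafSet({list(self.labels)!r})"

    def issubset(self, other: "LeafSet") -> bool:
        return set(self.labels) <= set(other.labels)

    def mask_of(self, labels: Iterable[str]) -> int:
        m = 0
        for lab in labels:
            m |= 1 << self.index[lab]
        return m

    def labels_of(self, mask: int) -> tuple[str, ...]:
        return tuple(lab for i, lab in enumerate(self.labels) if mask >> i & 1)


class Split:
    """A bipartition ``G | L\\G`` of a leaf set, identifying one edge.

    The stored mask is the block *not* containing the first leaf of the
    universe, so two Split objects are equal iff they denote the same
    bipartition of the same universe.
    """

    __slots__ = ("universe", "mask")

    def __init__(self, universe: LeafSet, side: Iterable[str] | int):
        mask = side if isinstance(side, int) else universe.mask_of(side)
        full = universe.full_mask
        if mask & ~full:
            raise ValueError("side is not a subset of the universe")
        if mask & 1:  # canonical block excludes the first leaf
            mask = full & ~mask
        if mask == 0 or mask == full:
            raise ValueError("both blocks of a split must be non-empty")
        self.universe = universe
        self.mask = mask

    # -- basic protocol ----------------------------------------------------
    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Split)
            and self.mask == other.mask
            and self.universe.labels == other.universe.labels
        )

    def __hash__(self) -> int:
        return hash((self.mask, self.universe.labels))

    def __repr__(self) -> str:
        return f"Split({self})"

    def __str__(self) -> str:
        side = ",".join(self.universe.labels_of(self.display_mask))
        other = ",".join(self.universe.labels_of(self.universe.full_mask & ~self.display_mask))
        return f"{side}|{other}"

    # -- structure ---------------------------------------------------------
    @property
    def co_mask(self) -> int:
        return self.universe.full_mask & ~self.mask

    @property
    def display_mask(self) -> int:
        """The smaller block (ties broken lexicographically), as printed."""
        a, b = self.mask, self.co_mask
        ca, cb = a.bit_count(), b.bit_count()
        if ca < cb:
            return a
        if cb < ca:
            return b
        return a if self.universe.labels_of(a) < self.universe.labels_of(b) else b

    @property
    def side(self) -> tuple[str, ...]:
        return self.universe.labels_of(self.display_mask)

    @property
    def is_external(self) -> bool:
        n = len(self.universe)
        c = self.mask.bit_count()
        return c == 1 or c == n - 1

    def sort_key(self):
        """Deterministic ordering: by the display block's label tuple."""
        return self.universe.labels_of(self.display_mask)

    def compatible_with(self, other: "Split") -> bool:
        return splits_compatible(self, other)


def _masks_compatible(a: int, b: int, full: int) -> bool:
    return (a & b) == 0 or (a & ~b & full) == 0 or (b & ~a & full) == 0 or (a | b) == full


def splits_compatible(a: Split, b: Split) -> bool:
    """True iff the two bipartitions can occur in the same tree.

    Two splits are compatible iff one of the four pairwise block
    intersections is empty (equivalently, their blocks nest or are
    disjoint).  External splits (singleton blocks) are compatible with
    everything.
    """
    if a.universe.labels != b.universe.labels:
        raise ValueError("splits live on different universes")
    return _masks_compatible(a.mask, b.mask, a.universe.full_mask)


def is_valid_topology(splits: Iterable[Split], leaves: LeafSet) -> bool:
    """Whether a set of internal splits forms a legitimate tree topology.

    By the Splits Equivalence Theorem this holds iff the splits are
    pairwise compatible; a topology on ``l`` leaves can carry at most
    ``l - 3`` internal splits (equality for binary trees).
    """
    ss = list(splits)
    for s in ss:
        if s.universe.labels != leaves.labels:
            return False
    if len(set(ss)) != len(ss):
        return False
    if len(ss) > max(len(leaves) - 3, 0):
        return False
    full = leaves.full_mask
    for i in range(len(ss)):
        for j in range(i + 1, len(ss)):
            if not _masks_compatible(ss[i].mask, ss[j].mask, full):
                return False
    return True


def _order_splits(splits: Iterable[Split]) -> list[Split]:
    """External splits in leaf order, then internal splits in display order."""
    ext = sorted((s for s in splits if s.is_external), key=Split.sort_key)
    internal = sorted((s for s in splits if not s.is_external), key=Split.sort_key)
    return ext + internal


class Tree:
    """A phylogenetic tree: leaf set plus a split -> length map.

    This is the vector representation of a point in (the closure of) an
    orthant of BHV space: zero-length internal edges are retained, marking
    a point on the orthant's boundary.
    """

    __slots__ = ("leaves", "lengths")

    def __init__(self, leaves: LeafSet, lengths: Mapping[Split, float], validate: bool = True):
        self.leaves = leaves
        self.lengths = dict(lengths)
        if validate:
            self._validate()

    def _validate(self) -> None:
        n = len(self.leaves)
        ext = set()
        internal = []
        for s, w in self.lengths.items():
            if s.universe.labels != self.leaves.labels:
                raise ValueError(f"split {s} not over this tree's leaves")
            if w < 0:
                raise ValueError(f"negative length for split {s}")
            if s.is_external:
                ext.add(s)
            else:
                internal.append(s)
        if len(ext) != n:
            raise ValueError("every leaf must have exactly one external edge")
        if len(internal) > n - 3:
            raise ValueError("too many internal splits")
        full = self.leaves.full_mask
        for i in range(len(internal)):
            for j in range(i + 1, len(internal)):
                if not _masks_compatible(internal[i].mask, internal[j].mask, full):
                    raise ValueError(
                        f"incompatible splits {internal[i]} and {internal[j]}"
                    )

    # -- views -------------------------------------------------------------
    @property
    def internal_splits(self) -> list[Split]:
        return sorted((s for s in self.lengths if not s.is_external), key=Split.sort_key)

    @property
    def external_splits(self) -> list[Split]:
        return sorted((s for s in self.lengths if s.is_external), key=Split.sort_key)

    @property
    def all_splits(self) -> list[Split]:
        return _order_splits(self.lengths)

    @property
    def is_binary(self) -> bool:
        return len(self.lengths) == 2 * len(self.leaves) - 3

    def length_of(self, s: Split) -> float:
        return self.lengths.get(s, 0.0)

    def edge_vector(self) -> list[float]:
        """Lengths in canonical order (external by leaf, then internal)."""
        return [self.lengths[s] for s in self.all_splits]

    def topology(self) -> "OrthantTopology":
        return OrthantTopology(self.leaves, frozenset(self.internal_splits))

    def scaled(self, c: float) -> "Tree":
        return Tree(self.leaves, {s: c * w for s, w in self.lengths.items()}, validate=False)

    # -- equality ----------------------------------------------------------
    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Tree)
            and self.leaves == other.leaves
            and self.lengths == other.lengths
        )

    def __hash__(self) -> int:
        return hash((self.leaves, frozenset(self.lengths.items())))

    def approx_equal(self, other: "Tree", tol: float = 1e-9) -> bool:
        """Same leaf set and split sets, lengths within absolute ``tol``."""
        if self.leaves != other.leaves:
            return False
        if set(self.lengths) != set(other.lengths):
            return False
        return all(abs(w - other.lengths[s]) <= tol for s, w in self.lengths.items())

    def __repr__(self) -> str:
        return f"Tree({write_newick(self)!r})"


class OrthantTopology:
    """A topology orthant: a leaf set plus a compatible set of internal splits."""

    __slots__ = ("leaves", "internal_splits")

    def __init__(self, leaves: LeafSet, internal_splits: Iterable[Split], validate: bool = True):
        self.leaves = leaves
        self.internal_splits = frozenset(internal_splits)
        if validate and not is_valid_topology(self.internal_splits, leaves):
            raise ValueError("splits do not form a valid topology")

    @property
    def is_maximal(self) -> bool:
        return len(self.internal_splits) == len(self.leaves) - 3

    @property
    def all_splits(self) -> list[Split]:
        """All 2n-3 (if maximal) edges: externals by leaf, then internals."""
        ext = [Split(self.leaves, 1 << i) for i in range(len(self.leaves))]
        ext.sort(key=Split.sort_key)
        return ext + sorted(self.internal_splits, key=Split.sort_key)

    def tree(self, lengths: Mapping[Split, float]) -> Tree:
        """A tree in this orthant with the given lengths (0 where omitted)."""
        full = {s: float(lengths.get(s, 0.0)) for s in self.all_splits}
        return Tree(self.leaves, full, validate=False)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OrthantTopology)
            and self.leaves == other.leaves
            and self.internal_splits == other.internal_splits
        )

    def __hash__(self) -> int:
        return hash((self.leaves, self.internal_splits))

    def __repr__(self) -> str:
        inner = "; ".join(str(s) for s in sorted(self.internal_splits, key=Split.sort_key))
        return f"OrthantTopology({inner})"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(
    text: str,
    universe: Optional[LeafSet] = None,
    default_length: Optional[float] = None,
    keep_root: bool = False,
) -> Tree:
    """Parse a Newick string into an unrooted :class:`Tree`.

    A rooted input (basal bifurcation) is unrooted by default: the two
    root-incident edges induce the same bipartition and their lengths are
    summed.  With ``keep_root=True`` the root is instead materialized as a
    pseudo-leaf named ``__root__`` attached with a zero-length edge, so the
    rooted tree is represented faithfully in a space with one extra leaf.

    Internal node labels / bootstrap values and bracket comments are
    accepted and discarded.  Edges without a length raise unless
    ``default_length`` is given.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            file=io.StringIO(text),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc

    leaf_nodes = [nd for nd in dtree.leaf_node_iter()]
    labels = []
    for nd in leaf_nodes:
        if nd.taxon is None or not nd.taxon.label:
            raise ValueError("leaf without a label")
        labels.append(nd.taxon.label)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels")
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")

    if keep_root:
        labels = labels + [ROOT_PSEUDO_LEAF]
    leaves = LeafSet(labels)
    if universe is not None:
        for lab in labels:
            if lab not in universe and lab != ROOT_PSEUDO_LEAF:
                raise ValueError(f"leaf {lab!r} not in the declared universe")

    # mask of leaves below each node (the root pseudo-leaf, if any, is "above")
    below: dict = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = 1 << leaves.index[nd.taxon.label]
        else:
            m = 0
            for ch in nd.child_nodes():
                m |= below[ch]
            below[nd] = m

    real_full = leaves.full_mask
    if keep_root:
        real_full &= ~(1 << leaves.index[ROOT_PSEUDO_LEAF])

    sums: dict[Split, float] = {}
    root = dtree.seed_node
    for nd in dtree.preorder_node_iter():
        if nd is root:
            continue
        mask = below[nd]
        if mask == 0 or mask == real_full and not keep_root:
            continue  # root edge of an already-unrooted representation
        w = nd.edge.length
        if w is None:
            if default_length is None:
                raise ValueError("edge without a branch length")
            w = default_length
        if w < 0:
            raise ValueError("negative branch length")
        s = Split(leaves, mask)
        sums[s] = sums.get(s, 0.0) + float(w)

    if keep_root:
        s_root = Split(leaves, 1 << leaves.index[ROOT_PSEUDO_LEAF])
        sums[s_root] = sums.get(s_root, 0.0)

    return Tree(leaves, sums)


def write_newick(tree: Tree, precision: int = 12) -> str:
    """Serialize a tree to Newick, deterministically.

    The tree is written anchored at the node adjacent to the
    lexicographically first leaf; children are ordered by the smallest leaf
    they contain, so equal trees always serialize identically.  Zero
    lengths are written out (an orthant-boundary point round-trips).
    """
    leaves = tree.leaves
    anchor_bit = 1
    fmt = lambda x: format(float(x), f".{precision}g")  # noqa: E731

    # blocks not containing the anchor, largest first, for nesting
    items = []
    for s in tree.internal_splits:
        m = s.mask if not (s.mask & anchor_bit) else s.co_mask
        items.append((m, tree.lengths[s]))
    items.sort(key=lambda t: -t[0].bit_count())

    children: dict[int, list[int]] = {-1: []}  # -1 is the root scope
    for m, _ in items:
        # find the smallest already-placed block strictly containing m
        best = -1
        for m2, _ in items:
            if m2 != m and m & ~m2 == 0 and m2 in children:
                if best == -1 or m2 & ~best == 0:
                    best = m2
        children.setdefault(best, []).append(m)
        children[m] = []
    lengths = {m: w for m, w in items}

    ext = {}
    for s in tree.external_splits:
        m = s.mask if s.mask.bit_count() == 1 else s.co_mask
        ext[m] = tree.lengths[s]

    def min_leaf(m: int) -> int:
        return (m & -m).bit_length()

    def render(m: int) -> str:
        if m.bit_count() == 1:
            lab = leaves.labels_of(m)[0]
            return f"{lab}:{fmt(ext[m])}"
        covered = 0
        parts = []
        for c in children[m]:
            covered |= c
            parts.append((min_leaf(c), f"{render(c)}:{fmt(lengths[c])}"))
        rest = m & ~covered
        while rest:
            bit = rest & -rest
            parts.append((min_leaf(bit), render(bit)))
            rest &= ~bit
        parts.sort()
        return "(" + ",".join(p for _, p in parts) + ")"

    # top level: the anchor leaf plus the maximal blocks and uncovered leaves
    covered = 0
    parts = [(1, render(anchor_bit))]
    for c in children[-1]:
        covered |= c
        parts.append((min_leaf(c), f"{render(c)}:{fmt(lengths[c])}"))
    rest = leaves.full_mask & ~covered & ~anchor_bit
    while rest:
        bit = rest & -rest
        parts.append((min_leaf(bit), render(bit)))
        rest &= ~bit
    parts.sort()
    return "(" + ",".join(p for _, p in parts) + ");"
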