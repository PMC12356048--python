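import pytest

from extspace.trees import LeafSet, OrthantTopology, Split, Tree


def make_tree(universe_labels: str | list, entries: list[tuple[str | tuple, float]]) -> Tree:
    """Build a tree from (split-side, length) pairs over a label universe."""
    L = LeafSet(universe_labels)
    return Tree(L, {Split(L, side): float(w) for side, w in entries})


@pytest.fixture(scope="session")
def worked_example_small():
    """The 4-leaf tree, its 7-leaf orthant, and the expected linear system
    (the quartet-in-a-7-leaf-space worked example used throughout)."""
    N = LeafSet("ABCDEFG")
    orthant = OrthantTopology(
        N, [Split(N, "AB"), Split(N, "CDE"), Split(N, "DE"), Split(N, "FG")]
    )
    tree = make_tree("ABCD", [("A", 2), ("B", 2), ("C", 1), ("D", 3), ("AB", 4)])
    return {"N": N, "orthant": orthant, "tree": tree}


@pytest.fixture(scope="session")
def worked_example_pair(worked_example_small):
    """Adds the second tree (5 leaves) and its orthant, forming the pair
    whose mutually restricted system is checked against printed values."""
    N = worked_example_small["N"]
    orthant2 = OrthantTopology(
        N, [Split(N, "AB"), Split(N, "ABC"), Split(N, "EFG"), Split(N, "FG")]
    )
    tree2 = make_tree(
        "ABCFG",
        [("A", 1), ("B", 1), ("C", 2), ("F", 2), ("G", 2), ("AB", 3), ("FG", 3)],
    )
    return {**worked_example_small, "orthant2": orthant2, "tree2": tree2}
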