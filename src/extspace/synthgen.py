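"""Simulation fixtures: random binary trees and paired-tree scenarios.

Edge lengths follow the study's two regimes: a low-variance lognormal
(mean 5, variance 1 of the lognormal variable itself) and a long-branch
mixture, 75% lognormal(mean 5, var 1) + 25% lognormal(mean 60, var 10).
Topologies are sampled uniformly by sequential random attachment.  All
sampling is driven by numpy Generators derived from a single master seed
through independent substreams, so a (scenario, seed) pair reproduces the
same fixture everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .trees import LeafSet, Split, Tree

__all__ = ["LengthModel", "Scenario", "PRESETS", "random_binary_tree", "make_scenario_pair"]

#: Table of scenario presets: (|L1 u L2|, |L1|, |L2|)
PRESETS: dict[str, tuple[int, int, int]] = {
    "a": (7, 6, 4),
    "b": (7, 6, 4),
    "c": (7, 5, 4),
    "d": (10, 9, 8),
    "e": (10, 8, 8),
    "f": (10, 8, 7),
}


def _lognormal_params(mean: float, var: float, parameterization: str) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal.

    With ``parameterization="lognormal"`` the given mean/variance are those
    of the lognormal variable itself and are back-solved; with
    ``"underlying"`` they are taken as the normal's mu and sigma^2.
    """
    if parameterization == "underlying":
        return mean, math.sqrt(var)
    if parameterization != "lognormal":
        raise ValueError("parameterization must be 'lognormal' or 'underlying'")
    sigma2 = math.log1p(var / mean**2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass
class LengthModel:
    """Edge-length distribution: 'unimodal' or 'bimodal' (75/25 mixture)."""

    kind: str = "unimodal"
    parameterization: str = "lognormal"
    heavy_weight: float = 0.25

    def __post_init__(self):
        if self.kind not in ("unimodal", "bimodal"):
            raise ValueError("kind must be 'unimodal' or 'bimodal'")
        if not 0.0 <= self.heavy_weight <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        mu1, s1 = _lognormal_params(5.0, 1.0, self.parameterization)
        draws = rng.lognormal(mu1, s1, size=size)
        if self.kind == "bimodal":
            mu2, s2 = _lognormal_params(60.0, 10.0, self.parameterization)
            heavy = rng.random(size) < self.heavy_weight
            draws = np.where(heavy, rng.lognormal(mu2, s2, size=size), draws)
        return draws


@dataclass
class Scenario:
    """Leaf-count triple (n = |L1 u L2|, l1, l2) plus the master seed."""

    n: int
    l1: int
    l2: int
    seed: int = 0

    def __post_init__(self):
        if not (3 <= self.l1 <= self.n and 3 <= self.l2 <= self.n):
            raise ValueError("need 3 <= l1, l2 <= n")
        if self.l1 + self.l2 < self.n:
            raise ValueError("leaf sets of these sizes cannot cover their union")

    @property
    def overlap(self) -> int:
        return self.l1 + self.l2 - self.n

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "Scenario":
        n, l1, l2 = PRESETS[name]
        return cls(n, l1, l2, seed)


def random_binary_tree(
    leaves: LeafSet,
    model: Optional[LengthModel] = None,
    seed: int | np.random.Generator = 0,
) -> Tree:
    """A uniform random binary topology on ``leaves`` with i.i.d. lengths.

    Leaves are attached one at a time in lexicographic order, choosing
    uniformly among the 2m-3 edges of the growing tree, which makes every
    binary topology equally likely.  Deterministic given the seed.
    """
    if len(leaves) < 3:
        raise ValueError("need at least 3 leaves")
    model = model or LengthModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    labs = leaves.labels
    # blocks not containing the anchor (first leaf), as in cluster enumeration
    blocks = [0b010, 0b100, 0b110]
    for i in range(3, len(labs)):
        x_bit = 1 << i
        p = blocks[rng.integers(len(blocks))]
        new_blocks = [x_bit, p, p | x_bit]
        for h in blocks:
            if h != p:
                new_blocks.append(h | x_bit if (p & ~h) == 0 else h)
        blocks = sorted(new_blocks)

    splits = [Split(leaves, m) for m in blocks]
    draws = model.sample(rng, len(splits))
    return Tree(leaves, {s: float(w) for s, w in zip(splits, draws)})


def make_scenario_pair(
    sc: Scenario, model: Optional[LengthModel] = None
) -> tuple[Tree, Tree]:
    """Two independent random trees whose leaf sets realize the scenario.

    The union leaf set is ``L01..Lnn``; the shared leaves and the split of
    the remainder are drawn from the scenario's seed, then each tree's
    topology and lengths are drawn from independent substreams.
    """
    model = model or LengthModel()
    ss = np.random.SeedSequence(sc.seed)
    rng_sets, rng1, rng2 = (np.random.default_rng(s) for s in ss.spawn(3))

    names = [f"L{i+1:02d}" for i in range(sc.n)]
    perm = list(rng_sets.permutation(sc.n))
    shared = [names[i] for i in perm[: sc.overlap]]
    rest = [names[i] for i in perm[sc.overlap:]]
    only1 = rest[: sc.l1 - sc.overlap]
    only2 = rest[sc.l1 - sc.overlap:]
    assert len(only2) == sc.l2 - sc.overlap

    t1 = random_binary_tree(LeafSet(shared + only1), model, rng1)
    t2 = random_binary_tree(LeafSet(shared + only2), model, rng2)
    return t1, t2
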