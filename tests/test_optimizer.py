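"""Reduced gradient method: objective, gradient, line search, convergence."""

import numpy as np
import pytest

from extspace.extension import (
    build_reduced_system,
    connection_cluster,
    reconstruct_pair,
    tdr_project,
)
from extspace.geodesic import distance
from extspace.optimizer import (
    VariablePartition,
    gradient_delta,
    line_search,
    minimize_orthant_pair,
    objective_delta,
    reduced_gradient,
)
from extspace.synthgen import random_binary_tree
from extspace.trees import LeafSet

from oracles import polytope_minimum


def _example_system(worked_example_pair):
    ex = worked_example_pair
    return build_reduced_system(ex["tree"], ex["orthant"], ex["tree2"], ex["orthant2"])


def _random_system(seed, n=6, l1=4, l2=4):
    """A random orthant-pair system from two random trees in a common space."""
    rng = np.random.default_rng(seed)
    labels = [chr(65 + i) for i in range(n)]
    all_subsets = labels
    t1 = random_binary_tree(LeafSet(labels[:l1]), seed=seed)
    t2 = random_binary_tree(LeafSet(labels[n - l2:]), seed=seed + 10_000)
    N = LeafSet(labels)
    c1 = list(connection_cluster(t1, N))
    c2 = list(connection_cluster(t2, N))
    O1 = c1[rng.integers(len(c1))]
    O2 = c2[rng.integers(len(c2))]
    return build_reduced_system(t1, O1, t2, O2)


def _interior_point(sys, rng):
    x = np.zeros(sys.n_vars)
    rows = sys.row_of_var
    for r in range(sys.M.shape[0]):
        idx = np.where(rows == r)[0]
        x[idx] = rng.dirichlet(np.ones(len(idx)) * 5.0) * sys.v[r]
    return x


class TestObjective:
    def test_zero_for_identical_pair(self):
        L = LeafSet("ABCDE")
        t = random_binary_tree(L, seed=0)
        sys = build_reduced_system(t, t.topology(), t, t.topology())
        assert objective_delta(sys.v, sys) == pytest.approx(0.0, abs=1e-15)

    def test_matches_squared_geodesic_distance(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            sys = _random_system(seed)
            x = _interior_point(sys, rng)
            a, b = reconstruct_pair(x, sys, check=False)
            assert objective_delta(x, sys, check_feasible=False) == pytest.approx(
                distance(a, b) ** 2, abs=1e-10
            )

    def test_infeasible_point_rejected(self, worked_example_pair):
        sys = _example_system(worked_example_pair)
        with pytest.raises(ValueError):
            objective_delta(sys.initial_point() + 1.0, sys)


class TestGradient:
    def test_common_consequential_edge_entries(self):
        # a shared-orthant pair: every entry is 2(x1 - x2) on tree 1's side
        L = LeafSet("ABCDE")
        t1 = random_binary_tree(L, seed=1)
        t2 = random_binary_tree(L, seed=1)  # same topology, same lengths
        t2 = t2.scaled(1.0)
        sys = build_reduced_system(t1, t1.topology(), t2, t2.topology())
        x = np.array(list(sys.v[:7]) + list(sys.v[7:]))
        x[0], x[7] = 3.0, 5.0  # same edge, lengths 3 and 5
        g, undef = gradient_delta(x, sys, check_feasible=False)
        assert g[0] == pytest.approx(-4.0)
        assert g[7] == pytest.approx(4.0)
        assert not undef.any()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        sys = _random_system(seed)
        x = _interior_point(sys, rng)
        g, undef = gradient_delta(x, sys, check_feasible=False)
        h = 1e-6
        fd = np.zeros_like(g)
        for j in range(sys.n_vars):
            e = np.zeros(sys.n_vars)
            e[j] = h
            fd[j] = (
                objective_delta(x + e, sys, check_feasible=False)
                - objective_delta(x - e, sys, check_feasible=False)
            ) / (2 * h)
        keep = ~undef
        err = np.abs(g[keep] - fd[keep]) / np.maximum(1.0, np.abs(fd[keep]))
        assert err.max() <= 1e-4


class TestReducedGradient:
    def test_empty_free_set(self, worked_example_pair):
        sys = _example_system(worked_example_pair)
        part = VariablePartition(D=list(range(sys.M.shape[0])), F=[], N=[])
        assert reduced_gradient(np.ones(sys.n_vars), sys, part).size == 0

    def test_identity_system_passthrough(self):
        L = LeafSet("ABCDE")
        t1 = random_binary_tree(L, seed=1)
        t2 = random_binary_tree(L, seed=2)
        sys = build_reduced_system(t1, t1.topology(), t2, t2.topology())
        part = VariablePartition(D=list(range(14)), F=[], N=[])
        # degenerate: every variable dependent; with a fake free split the
        # projection reduces to the plain gradient difference
        grad = np.arange(14, dtype=float)
        assert reduced_gradient(grad, sys, part).size == 0

    def test_agrees_with_row_structure_shortcut(self, worked_example_pair):
        # the generic dense solve must equal grad_j - grad_dep(row(j))
        sys = _example_system(worked_example_pair)
        rng = np.random.default_rng(0)
        rows = sys.row_of_var
        m = sys.M.shape[0]
        dep, seen = [], set()
        for j in range(sys.n_vars):
            if rows[j] not in seen:
                seen.add(rows[j])
                dep.append(j)
        free = [j for j in range(sys.n_vars) if j not in dep]
        grad = rng.normal(size=sys.n_vars)
        part = VariablePartition(D=dep, F=free, N=[])
        got = reduced_gradient(grad, sys, part)
        dep_of_row = {int(rows[j]): j for j in dep}
        expect = np.array([grad[j] - grad[dep_of_row[int(rows[j])]] for j in free])
        assert np.allclose(got, expect, atol=1e-12)


class TestLineSearch:
    def _shared_orthant_system(self):
        L = LeafSet("ABCDE")
        t1 = random_binary_tree(L, seed=3)
        t2 = random_binary_tree(L, seed=3).scaled(2.0)
        N = LeafSet("ABCDEF")
        O = list(connection_cluster(t1, N))[0]
        return build_reduced_system(t1, O, t2, O)

    def test_quadratic_minimizer_recovered(self):
        # same orthant pair: delta is a quadratic along any line; compare
        # against the analytic minimizer of f(tau) = sum (a_i + tau b_i)^2
        sys = self._shared_orthant_system()
        rng = np.random.default_rng(1)
        x = _interior_point(sys, rng)
        d = np.zeros(sys.n_vars)
        rows = sys.row_of_var
        for r in range(sys.M.shape[0]):
            idx = np.where(rows == r)[0]
            if len(idx) > 1:
                step = rng.normal(size=len(idx))
                d[idx] = step - step.mean()
        g0, _ = gradient_delta(x, sys, check_feasible=False)
        if float(g0 @ d) > 0:
            d = -d
        tau = line_search(x, d, sys, grad=g0, tol=1e-12)
        # analytic: f(tau) quadratic -> tau* = -f'(0) / f''(0); differences
        # of a quadratic are exact for any h, so take h large for stability
        h = 1e-2
        f = lambda t: objective_delta(x + t * d, sys, check_feasible=False)
        d1 = (f(h) - f(-h)) / (2 * h)
        d2 = (f(h) - 2 * f(0) + f(-h)) / h**2
        analytic = np.clip(-d1 / d2, 0, None)
        neg = d < 0
        tau_max = float(np.min(-x[neg] / d[neg]))
        assert tau == pytest.approx(min(analytic, tau_max), abs=1e-8)

    def test_zero_direction_returns_zero(self, worked_example_pair):
        sys = _example_system(worked_example_pair)
        assert line_search(sys.initial_point(), np.zeros(sys.n_vars), sys) == 0.0

    def test_ascent_direction_raises(self):
        sys = self._shared_orthant_system()
        x = _interior_point(sys, np.random.default_rng(2))
        g, _ = gradient_delta(x, sys, check_feasible=False)
        rows = sys.row_of_var
        d = np.zeros(sys.n_vars)
        for r in range(sys.M.shape[0]):
            idx = np.where(rows == r)[0]
            if len(idx) > 1:
                gr = g[idx] - g[idx].mean()
                d[idx] = gr  # along the gradient: ascent
        if float(g @ d) <= 0:
            pytest.skip("degenerate instance: gradient orthogonal to rows")
        with pytest.raises(ValueError):
            line_search(x, d, sys, grad=g)

    def test_step_clamped_at_boundary(self):
        # construct a descent direction whose optimum lies past the boundary
        sys = self._shared_orthant_system()
        x = _interior_point(sys, np.random.default_rng(3))
        g, _ = gradient_delta(x, sys, check_feasible=False)
        rows = sys.row_of_var
        d = np.zeros(sys.n_vars)
        for r in range(sys.M.shape[0]):
            idx = np.where(rows == r)[0]
            if len(idx) > 1:
                gr = g[idx] - g[idx].mean()
                d[idx] = -gr
        neg = d < 0
        if not neg.any():
            pytest.skip("degenerate instance: no boundary in this direction")
        tau = line_search(x, d, sys, grad=g)
        tau_max = float(np.min(-x[neg] / d[neg]))
        assert 0.0 <= tau <= tau_max + 1e-15


class TestMinimizeOrthantPair:
    def test_identical_leaf_sets_reduce_to_bhv_distance(self):
        L = LeafSet("ABCDEF")
        t1 = random_binary_tree(L, seed=4)
        t2 = random_binary_tree(L, seed=44)
        sys = build_reduced_system(t1, t1.topology(), t2, t2.topology())
        res = minimize_orthant_pair(sys)
        assert res.converged
        assert res.iterations == 0
        assert res.distance == pytest.approx(distance(t1, t2), abs=1e-12)

    def test_intersecting_extension_spaces_give_zero(self):
        # t2 is the restriction of an extension of t1 living in O2
        N = LeafSet("ABCDEF")
        full = random_binary_tree(N, seed=7)
        t1 = tdr_project(full, LeafSet("ABCD"))
        t2 = tdr_project(full, LeafSet("ABCE"))
        O = full.topology()
        sys = build_reduced_system(t1, O, t2, O)
        res = minimize_orthant_pair(sys)
        assert res.distance <= 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_polytope_brute_force(self, seed):
        sys = _random_system(seed, n=6, l1=4, l2=4)
        res = minimize_orthant_pair(sys)
        assert res.converged
        brute = polytope_minimum(sys)
        assert res.distance <= brute + 1e-5
        assert abs(res.distance - brute) <= 2e-4  # grid resolution limited

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_feasible_and_certified(self, seed):
        sys = _random_system(seed + 100, n=6, l1=5, l2=4)
        res = minimize_orthant_pair(sys)
        assert res.converged
        assert sys.is_feasible(res.x_star, tol=1e-8)
        assert res.certificate_min >= -1e-7
        # result never below the true minimum of sampled feasible points
        rng = np.random.default_rng(seed)
        for _ in range(20):
            x = _interior_point(sys, rng)
            assert res.objective <= objective_delta(x, sys, check_feasible=False) + 1e-9
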