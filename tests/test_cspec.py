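"""The convex clustering core: solver, lambda/k tuning, power mismatch.

Two independent oracles check the relaxation: scipy's trust-constr on the
identical program (dual numerical route), and exhaustive enumeration of
contiguous binary indicator vectors on small graphs (combinatorial route).
"""

import itertools

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

import silencemap as sm
from silencemap._qp import project_box_budget, solve_qp
from silencemap.cspec import (_tune_lambda, build_power_constraints,
                              estimate_size, power_mismatch, smallest_k,
                              solve_cspec, tune_lambda)
from silencemap.geometry import NeighborGraph, SourceGrid


def path_graph(p, w=1.0):
    W = np.zeros((p, p))
    for i in range(p - 1):
        W[i, i + 1] = W[i + 1, i] = w
    return NeighborGraph(W=W, z=1, theta=1.0)


def line_grid(p):
    pos = np.column_stack([np.arange(p, dtype=float) * 5.0,
                           np.zeros(p), np.zeros(p)])
    return SourceGrid(pos, np.array(["R"] * p, dtype=object), np.full(p, -1))


def connected_k_subsets(W, k):
    """All k-subsets inducing a connected subgraph of W."""
    p = W.shape[0]
    out = []
    for sub in itertools.combinations(range(p), k):
        sub = list(sub)
        adj = W[np.ix_(sub, sub)] > 0
        seen = {0}
        frontier = [0]
        while frontier:
            i = frontier.pop()
            for j in range(k):
                if adj[i, j] and j not in seen:
                    seen.add(j)
                    frontier.append(j)
        if len(seen) == k:
            out.append(tuple(sub))
    return out


def binary_objective(beta, L, subset, lam):
    g = np.ones(beta.size)
    g[list(subset)] = 0.0
    return beta @ (1 - g) + lam * (1 - g) @ L @ (1 - g)


class TestQPSolver:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_trust_constr(self, seed):
        rng = np.random.default_rng(seed)
        p = 20
        B = rng.normal(size=(p, p))
        P = B @ B.T / p
        q = rng.normal(size=p)
        A = np.vstack([np.eye(p), np.ones((1, p)), rng.normal(size=(2, p))])
        l = np.concatenate([np.zeros(p), [0.0], [-1.0, -2.0]])
        u = np.concatenate([np.ones(p), [p - 3.0], [1.0, 2.0]])
        res = solve_qp(P, q, A, l, u, box_budget=p)
        ref = minimize(lambda x: 0.5 * x @ P @ x + q @ x, np.full(p, 0.5),
                       jac=lambda x: P @ x + q, hess=lambda x: P,
                       method="trust-constr",
                       constraints=LinearConstraint(A[p:], l[p:], u[p:]),
                       bounds=[(0, 1)] * p,
                       options={"gtol": 1e-10, "xtol": 1e-12})
        # the interior-point solve may be (slightly) tighter than the
        # reference's own tolerance, but never worse
        assert res.objective <= ref.fun + 1e-6
        assert res.objective == pytest.approx(ref.fun, abs=2e-3)
        assert np.allclose(res.x, ref.x, atol=5e-3)

    def test_generic_path_agrees_with_structured(self):
        rng = np.random.default_rng(42)
        p = 12
        P = np.diag(rng.uniform(0.5, 2, p))
        q = rng.normal(size=p)
        A = np.vstack([np.eye(p), np.ones((1, p))])
        l = np.concatenate([np.zeros(p), [0.0]])
        u = np.concatenate([np.ones(p), [p - 2.0]])
        a = solve_qp(P, q, A, l, u, box_budget=p)
        b = solve_qp(P, q, A, l, u, box_budget=None)
        assert np.allclose(a.x, b.x, atol=1e-6)

    def test_projection_box_budget(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = rng.uniform(-0.5, 1.5, 30)
            budget = rng.uniform(1, 25)
            proj = project_box_budget(g, budget)
            assert np.all(proj >= 0) and np.all(proj <= 1)
            assert proj.sum() <= budget + 1e-9
            # projection is optimal: compare against trust-constr
            ref = minimize(lambda x: 0.5 * np.sum((x - g) ** 2),
                           np.clip(g, 0, 1), method="trust-constr",
                           constraints=LinearConstraint(
                               np.ones((1, 30)), 0, budget),
                           bounds=[(0, 1)] * 30)
            assert np.sum((proj - g) ** 2) <= np.sum((ref.x - g) ** 2) + 1e-6


class TestSolveCSpec:
    def test_k0_lambda0_gives_all_ones(self):
        beta = np.array([0.3, 0.1, 0.5, 0.2])
        sol = solve_cspec(beta, np.zeros((4, 4)), k=0, lam=0.0)
        assert np.allclose(sol.g, 1.0, atol=1e-6)
        assert sol.objective_terms[0] == pytest.approx(0.0, abs=1e-5)
        assert sol.silent_set.size == 0

    def test_lambda0_picks_smallest_beta(self):
        beta = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        sol = solve_cspec(beta, np.zeros((6, 6)), k=2, lam=0.0)
        assert set(sol.silent_set) == {0, 1}
        # LP structure: the optimum zeroes exactly the two cheap coordinates
        assert np.allclose(np.sort(sol.g)[:2], 0.0, atol=1e-5)

    def test_path_graph_matches_combinatorial_optimum(self):
        g = path_graph(8)
        beta = np.ones(8)
        beta[[4, 5]] = 0.05
        lam = 0.3
        sol = solve_cspec(beta, g, k=2, lam=lam)
        assert set(sol.silent_set) == {4, 5}
        best = min(connected_k_subsets(g.W, 2),
                   key=lambda s: binary_objective(beta, g.L, s, lam))
        assert set(best) == set(sol.silent_set)

    def test_feasibility_invariant(self, small_grid):
        rng = np.random.default_rng(2)
        g = sm.build_graph(small_grid, 6)
        for k in (3, 10, 25):
            beta = rng.uniform(0, 1, small_grid.p)
            sol = solve_cspec(beta, g, k=k, lam=0.1)
            assert np.all(sol.g >= -1e-6) and np.all(sol.g <= 1 + 1e-6)
            assert sol.g.sum() <= small_grid.p - k + 1e-6

    def test_power_constraints_never_decrease_objective(self):
        rng = np.random.default_rng(3)
        p, n = 40, 12
        A_t = rng.normal(size=(n, p))
        C_full = np.eye(p)
        var_y = np.einsum("ij,jk,ik->i", A_t, C_full, A_t) * 0.7
        pc = build_power_constraints(A_t, C_full, np.zeros(n), var_y,
                                     np.arange(4), zeta_floor_rel=0.05)
        beta = rng.uniform(0, 1, p)
        L = path_graph(p).L
        free = solve_cspec(beta, L, k=5, lam=0.05)
        tight = solve_cspec(beta, L, k=5, lam=0.05, power_constraints=pc)
        obj = lambda s: s.objective_terms[0] + 0.05 * s.objective_terms[1]
        assert obj(tight) >= obj(free) - 1e-6

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            solve_cspec(np.ones(4), np.zeros((4, 4)), k=4, lam=0.1)
        with pytest.raises(ValueError):
            solve_cspec(np.ones(4), np.zeros((4, 4)), k=1, lam=-1.0)

    def test_tie_break_lowest_index(self):
        g = np.array([0.5, 0.2, 0.2, 0.9])
        assert np.array_equal(smallest_k(g, 2), [1, 2])
        assert np.array_equal(smallest_k(np.zeros(4), 2), [0, 1])


class TestTuneLambda:
    def test_single_element_grid(self):
        beta = np.array([0.1, 0.9, 0.9, 0.9])
        assert tune_lambda(beta, path_graph(4), 1, [0.7]) == 0.7

    def test_matches_direct_grid_evaluation(self):
        rng = np.random.default_rng(4)
        g = path_graph(10)
        beta = rng.uniform(0, 1, 10)
        grid = np.geomspace(1e-3, 10, 6)
        lam_star, sols = _tune_lambda(beta, g, 3, grid)
        lin = np.array([sols[float(l)].objective_terms[0] for l in grid]) ** 2
        quad = np.array([sols[float(l)].objective_terms[1] for l in grid]) ** 2
        total = lin / lin.max() + quad / quad.max()
        assert lam_star == pytest.approx(grid[np.argmin(total)])

    def test_beta_scaling_leaves_lambda_star_unchanged(self):
        rng = np.random.default_rng(5)
        g = path_graph(12)
        beta = rng.uniform(0.1, 1, 12)
        beta[[5, 6]] = 0.01
        grid = np.geomspace(1e-3, 1.0, 5)
        # scale lambda grid along with beta: the program is identical up to
        # the constant, so the normalized tuning objective is unchanged
        lam1 = tune_lambda(beta, g, 2, grid)
        lam2 = tune_lambda(7.0 * beta, g, 2, 7.0 * grid)
        assert lam2 == pytest.approx(7.0 * lam1)


class TestEstimateSize:
    def _exact_instance(self, k0):
        """Low-res forward-consistent instance: Var(y) generated exactly by
        a size-k0 region of uncorrelated unit-variance sources."""
        grid = line_grid(24)
        rng = np.random.default_rng(6)
        A_t = rng.normal(size=(10, 24))
        truth = np.arange(8, 8 + k0)
        active = np.setdiff1d(np.arange(24), truth)
        var_y = np.sum(A_t[:, active] ** 2, axis=1)
        stats = sm.ChannelStats(var_y=var_y,
                                var_mu=np.zeros(24),
                                C_z_hat=np.zeros((10, 10)), A_tilde=A_t)
        beta = np.ones(24)
        beta[truth] = 0.0
        graphs = lambda k: sm.build_graph(grid, max(1, min(k, 23)))
        return grid, A_t, stats, beta, graphs, truth

    def test_recovers_true_size(self):
        k0 = 4
        grid, A_t, stats, beta, graphs, truth = self._exact_instance(k0)
        est = estimate_size(beta, graphs, [2, 3, 4, 6, 8], A_t, stats,
                            lambda_grid=np.geomspace(1e-4, 1, 5))
        assert est.k_hat == k0
        assert set(est.solutions[k0].silent_set) == set(truth)

    def test_singleton_grid(self):
        grid, A_t, stats, beta, graphs, truth = self._exact_instance(4)
        est = estimate_size(beta, graphs, [4], A_t, stats,
                            lambda_grid=np.array([0.01]))
        assert est.k_hat == 4

    def test_cost_at_true_size_below_double(self):
        k0 = 4
        grid, A_t, stats, beta, graphs, truth = self._exact_instance(k0)
        est = estimate_size(beta, graphs, [k0, 2 * k0], A_t, stats,
                            lambda_grid=np.geomspace(1e-4, 1, 5))
        assert est.costs[k0] <= est.costs[2 * k0]


class TestPowerMismatch:
    def test_zero_for_proportional_model(self):
        rng = np.random.default_rng(7)
        n, p = 8, 15
        A_t = rng.normal(size=(n, p))
        C = np.eye(p)
        modeled = np.einsum("ij,jk,ik->i", A_t, C, A_t)
        sigma_z2 = rng.uniform(0.1, 0.2, n)
        var_y = 5.0 * modeled + sigma_z2  # observed = 5 x modeled + noise
        stats = sm.ChannelStats(var_y=var_y, var_mu=np.zeros(p),
                                C_z_hat=np.diag(sigma_z2), A_tilde=A_t)
        assert power_mismatch(A_t, C, stats) == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(8)
        n, p = 6, 9
        A_t = rng.normal(size=(n, p))
        B = rng.normal(size=(p, p))
        C = B @ B.T
        var_y = rng.uniform(1, 2, n)
        sigma_z2 = rng.uniform(0.01, 0.1, n)
        stats = sm.ChannelStats(var_y=var_y, var_mu=np.zeros(p),
                                C_z_hat=np.diag(sigma_z2), A_tilde=A_t)
        got = power_mismatch(A_t, C, stats)
        modeled = np.array([A_t[i] @ C @ A_t[i] for i in range(n)])
        obs = var_y - sigma_z2
        expect = sum((modeled[i] / modeled.max()
                      - obs[i] / obs.max()) ** 2 for i in range(n))
        assert got == pytest.approx(expect, rel=1e-12)
        assert got >= 0.0

    def test_zero_model_rejected(self):
        stats = sm.ChannelStats(var_y=np.ones(3), var_mu=np.zeros(4),
                                C_z_hat=np.zeros((3, 3)),
                                A_tilde=np.ones((3, 4)))
        with pytest.raises(ValueError):
            power_mismatch(np.ones((3, 4)), np.zeros((4, 4)), stats)
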