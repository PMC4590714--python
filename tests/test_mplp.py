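"""MPLP dual coordinate descent: duality, monotonicity, decoding."""

import numpy as np

from seghog.mplp import (
    DualVariables,
    decode_primal,
    dual_objective,
    mplp_iterate,
    mplp_solve,
)
from seghog.solver import BoundaryProblem, brute_force, dcdp
from seghog.synthetic import generate_boundary_problem


def test_zero_dual_closed_form():
    prob = generate_boundary_problem(6, 5, 1, seed=0)
    lam = DualVariables.zeros(prob)
    assert np.isclose(dual_objective(prob, lam), prob.L.max(axis=1).sum())


def test_dual_objective_matches_direct_loop():
    prob = generate_boundary_problem(5, 4, 1, seed=1)
    rng = np.random.default_rng(2)
    lam = DualVariables(node=rng.normal(size=(5, 4)), edge=rng.normal(size=(5, 4)))
    m, n, s = 5, 4, 1
    node_term = 0.0
    for i in range(m):
        node_term += max(
            prob.L[i, p] + lam.node[i, p] + lam.edge[(i - 1) % m, p] for p in range(n)
        )
    edge_term = 0.0
    for i in range(m):
        edge_term += min(
            lam.node[i, p] + lam.edge[i, q]
            for p in range(n)
            for q in range(n)
            if abs(p - q) <= s
        )
    assert np.isclose(dual_objective(prob, lam), node_term - edge_term)


def test_weak_duality_and_monotone_descent():
    for k in range(10):
        rng = np.random.default_rng(k)
        m = int(rng.integers(4, 13))
        n = int(rng.integers(3, 9))
        s = int(rng.integers(0, 3))
        prob = generate_boundary_problem(m, n, s, seed=40 + k)
        opt = dcdp(prob).solution.objective
        for mode in ("mplp", "mplp_plus"):
            lam = DualVariables.zeros(prob)
            prev = dual_objective(prob, lam)
            for _ in range(40):
                lam = mplp_iterate(prob, lam, mode)
                psi = dual_objective(prob, lam)
                assert psi <= prev + 1e-9
                assert psi >= opt - 1e-9
                prev = psi


def test_fixed_point_at_convergence():
    prob = generate_boundary_problem(8, 6, 1, seed=7)
    lam = DualVariables.zeros(prob)
    for _ in range(2000):
        new = mplp_iterate(prob, lam, "mplp")
        delta = max(
            np.abs(new.node - lam.node).max(), np.abs(new.edge - lam.edge).max()
        )
        lam = new
        if delta < 1e-12:
            break
    again = mplp_iterate(prob, lam, "mplp")
    assert np.abs(again.node - lam.node).max() < 1e-9
    assert np.abs(again.edge - lam.edge).max() < 1e-9


def test_zero_dual_decodes_columnwise_max():
    prob = generate_boundary_problem(7, 5, 1, seed=11)
    sol = decode_primal(prob, DualVariables.zeros(prob))
    assert np.array_equal(sol.p, np.argmax(prob.L, axis=1) + 1)


def test_infeasible_decode_is_flagged_not_raised():
    L = np.zeros((4, 5))
    L[[0, 1, 2, 3], [0, 4, 0, 4]] = 10.0  # zigzag columnwise max
    prob = BoundaryProblem(L, varsigma=1)
    sol = decode_primal(prob, DualVariables.zeros(prob))
    assert not sol.feasible


def test_feasible_zigzag_converges_immediately():
    L = np.zeros((6, 5))
    L[:, 2] = 10.0  # columnwise max already cyclically feasible
    prob = BoundaryProblem(L, varsigma=1)
    res = mplp_solve(prob, "mplp")
    assert res.converged
    assert res.iterations == 1


def test_converged_decode_is_optimal():
    hits = 0
    for k in range(25):
        prob = generate_boundary_problem(12, 8, 1, seed=500 + k)
        opt = dcdp(prob).solution.objective
        res = mplp_solve(prob, "mplp", max_iters=5000)
        if res.converged:
            assert res.solution.feasible
            assert res.solution.objective == opt
            hits += 1
    assert hits >= 20  # LP relaxation of these instances is almost always tight


def test_nonconvergence_returns_best_feasible_with_flag():
    prob = generate_boundary_problem(12, 8, 1, seed=501)
    res = mplp_solve(prob, "mplp", max_iters=2)
    assert res.iterations <= 2
    assert isinstance(res.converged, bool)
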