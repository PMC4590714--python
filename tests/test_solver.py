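"""Exactness and structure of the cyclic-polygon solvers."""

import numpy as np
import pytest

from seghog.solver import (
    SCHEMES,
    BoundaryProblem,
    IndexInterval,
    brute_force,
    dcdp,
    edp,
    is_feasible,
    objective,
    solve_chain_dp,
    split_interval,
)
from seghog.synthetic import generate_boundary_problem, random_feasible_path


def _random_problem(k, m_max=8, n_max=6):
    rng = np.random.default_rng(k)
    m = int(rng.integers(3, m_max + 1))
    n = int(rng.integers(2, n_max + 1))
    s = int(rng.integers(0, 3))
    return generate_boundary_problem(m, n, s, seed=k)


# ---------------------------------------------------------------- objective


def test_objective_examples():
    zeros = BoundaryProblem(np.zeros((36, 5)))
    assert objective(np.full(36, 3), zeros) == 0.0
    ones = BoundaryProblem(np.ones((36, 5)))
    assert objective(np.full(36, 2), ones) == 36.0


def test_objective_matches_direct_loop():
    prob = generate_boundary_problem(4, 5, 1, seed=9)
    p = np.array([1, 2, 3, 4])
    expected = sum(prob.L[i, p[i] - 1] for i in range(4))
    assert objective(p, prob) == expected


def test_objective_rejects_out_of_range():
    prob = BoundaryProblem(np.zeros((3, 2)))
    with pytest.raises(ValueError):
        objective(np.array([1, 3, 1]), prob)


def test_feasibility_examples():
    prob = BoundaryProblem(np.zeros((5, 4)), varsigma=1)
    assert is_feasible(np.full(5, 2), prob)
    assert not is_feasible(np.array([1, 3, 1, 1, 1]), prob)
    # wrap constraint
    assert not is_feasible(np.array([1, 2, 3, 4, 4]), prob)


def test_feasibility_matches_direct_loop():
    rng = np.random.default_rng(5)
    for _ in range(50):
        prob = BoundaryProblem(np.zeros((6, 5)), varsigma=int(rng.integers(0, 3)))
        p = rng.integers(1, 6, size=6)
        direct = all(
            abs(int(p[i]) - int(p[(i + 1) % 6])) <= prob.varsigma for i in range(6)
        )
        assert is_feasible(p, prob) == direct


# ---------------------------------------------------------------- chain DP


def test_chain_dp_zero_scores():
    prob = BoundaryProblem(np.zeros((5, 4)))
    sol = solve_chain_dp(prob, IndexInterval(1, 4))
    assert sol.objective == 0.0


def test_chain_dp_single_column_is_cyclically_feasible():
    # with I0 = {h} the relaxed region equals the unrelaxed one
    for k in range(20):
        prob = _random_problem(k)
        h = 1 + k % prob.n
        sol = solve_chain_dp(prob, IndexInterval(h, h))
        assert sol.feasible
        assert sol.p[-1] == h


def test_chain_dp_matches_enumeration_over_relaxed_region():
    for k in range(30):
        rng = np.random.default_rng(k)
        prob = generate_boundary_problem(5, 4, 1, seed=300 + k)
        lo = int(rng.integers(1, 5))
        hi = int(rng.integers(lo, 5))
        I0 = IndexInterval(lo, hi)
        sol = solve_chain_dp(prob, I0)
        # enumerate the relaxed region directly
        best = -np.inf
        import itertools

        for cand in itertools.product(range(1, 5), repeat=5):
            p = np.array(cand)
            if not (lo <= p[-1] <= hi):
                continue
            if not (lo - 1 <= p[0] <= hi + 1):
                continue
            if np.any(np.abs(np.diff(p)) > 1):
                continue
            best = max(best, objective(p, prob))
        assert sol.objective == best


# ---------------------------------------------------------------- splitting


def test_half_split_printed_example():
    prob = BoundaryProblem(np.zeros((3, 12)))
    I1, I2 = split_interval(IndexInterval(7, 12), "half", prob, swap=False)
    assert (I1.lo, I1.hi) == (7, 9)
    assert (I2.lo, I2.hi) == (10, 12)


def test_half_split_swap_heuristic():
    L = np.zeros((3, 12))
    L[-1, 11] = 5.0  # best last-ray score in the second half
    prob = BoundaryProblem(L)
    I1, I2 = split_interval(IndexInterval(7, 12), "half", prob)
    assert (I1.lo, I1.hi) == (10, 12)  # swapped: promising side first


def test_max_split_printed_example():
    L = np.zeros((3, 12))
    L[-1, 7] = 9.0  # h* = 8
    prob = BoundaryProblem(L)
    I1, I2 = split_interval(IndexInterval(7, 12), "max", prob, swap=False)
    assert (I1.lo, I1.hi) == (7, 8)
    assert (I2.lo, I2.hi) == (9, 12)
    # cardinality swap leaves this division unchanged (2 <= 4)
    I1s, I2s = split_interval(IndexInterval(7, 12), "max", prob)
    assert (I1s.lo, I1s.hi) == (7, 8)


def test_max_split_empty_side_repair():
    L = np.zeros((3, 12))
    L[-1, 11] = 9.0  # h* = hi
    prob = BoundaryProblem(L)
    I1, I2 = split_interval(IndexInterval(7, 12), "max", prob, swap=False)
    assert (I2.lo, I2.hi) == (12, 12)
    assert (I1.lo, I1.hi) == (7, 11)


def test_adap_split_printed_example():
    prob = BoundaryProblem(np.zeros((3, 12)))
    p_L = np.array([9, 5, 12])  # first entry 9, last entry 12 -> cut at 10.5
    I1, I2 = split_interval(IndexInterval(7, 12), "adap", prob, p_L, swap=False)
    assert (I1.lo, I1.hi) == (7, 10)
    assert (I2.lo, I2.hi) == (11, 12)


def test_split_partition_property():
    rng = np.random.default_rng(0)
    for k in range(100):
        prob = generate_boundary_problem(4, 12, 1, seed=k)
        lo = int(rng.integers(1, 12))
        hi = int(rng.integers(lo + 1, 13))
        I0 = IndexInterval(lo, hi)
        p_L = rng.integers(1, 13, size=4)
        for scheme in SCHEMES:
            I1, I2 = split_interval(I0, scheme, prob, p_L)
            cover = sorted(
                list(range(I1.lo, I1.hi + 1)) + list(range(I2.lo, I2.hi + 1))
            )
            assert cover == list(range(lo, hi + 1))
            assert I1.card >= 1 and I2.card >= 1


def test_split_single_element_rejected():
    prob = BoundaryProblem(np.zeros((3, 5)))
    with pytest.raises(ValueError):
        split_interval(IndexInterval(3, 3), "half", prob)


# ---------------------------------------------------------------- DCDP / EDP


def test_dominant_column_solved_in_one_dp_call():
    L = np.zeros((10, 6))
    L[:, 3] = 5.0  # unique best column in every row
    rep = dcdp(BoundaryProblem(L), "adap")
    assert np.all(rep.solution.p == 4)
    assert rep.n_dp == 1


@pytest.mark.parametrize("scheme", SCHEMES)
def test_dcdp_matches_brute_force(scheme):
    for k in range(60):
        prob = _random_problem(k)
        bf = brute_force(prob)
        rep = dcdp(prob, scheme)
        assert rep.solution.objective == bf.objective
        assert rep.solution.feasible


def test_edp_matches_brute_force_and_counts_n():
    for k in range(60, 100):
        prob = _random_problem(k)
        rep = edp(prob)
        assert rep.solution.objective == brute_force(prob).objective
        assert rep.n_dp == prob.n


def test_dp_call_budget_at_reference_scale():
    for k in range(20):
        prob = generate_boundary_problem(36, 22, 1, seed=700 + k)
        for scheme in SCHEMES:
            rep = dcdp(prob, scheme)
            assert rep.n_dp <= 2 * 22 - 1


def test_pruning_soundness():
    for k in range(30):
        prob = _random_problem(k)
        for scheme in SCHEMES:
            with_p = dcdp(prob, scheme, prune=True)
            without = dcdp(prob, scheme, prune=False)
            assert with_p.solution.objective == without.solution.objective
            assert without.n_dp >= with_p.n_dp


def test_relaxation_upper_bounds_restriction():
    for k in range(30):
        prob = generate_boundary_problem(6, 5, 1, seed=900 + k)
        for lo in range(1, 6):
            for hi in range(lo, 6):
                I = IndexInterval(lo, hi)
                relaxed = solve_chain_dp(prob, I).objective
                best_restricted = max(
                    solve_chain_dp(prob, IndexInterval(h, h)).objective
                    for h in range(lo, hi + 1)
                )
                assert relaxed >= best_restricted - 1e-12


def test_varsigma_monotonicity_and_saturation():
    for k in range(20):
        prob0 = generate_boundary_problem(6, 5, 0, seed=1100 + k)
        prev = -np.inf
        for s in range(0, 6):
            obj = dcdp(BoundaryProblem(prob0.L, varsigma=s)).solution.objective
            assert obj >= prev
            prev = obj
        assert prev == prob0.L.max(axis=1).sum()  # s >= n-1: unconstrained


def test_planted_path_is_recovered():
    for k in range(20):
        rng = np.random.default_rng(k)
        path = random_feasible_path(12, 8, 1, rng)
        prob = generate_boundary_problem(12, 8, 1, seed=k, planted=path)
        rep = dcdp(prob, "adap")
        assert np.array_equal(rep.solution.p, path)


def test_infeasible_planted_path_rejected():
    with pytest.raises(ValueError):
        generate_boundary_problem(5, 6, 1, seed=0, planted=np.array([1, 4, 1, 1, 1]))


def test_brute_force_size_guard():
    with pytest.raises(ValueError):
        brute_force(BoundaryProblem(np.zeros((30, 22))))


def test_varsigma_zero_forces_constant_vectors():
    prob = generate_boundary_problem(3, 2, 0, seed=4)
    sol = brute_force(prob)
    assert len(set(sol.p.tolist())) == 1
    best_const = max(prob.L[:, c].sum() for c in range(2))
    assert sol.objective == best_const
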