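"""Exact solvers for the cyclic boundary-polygon optimization problem.

The segmentation stage selects one sample index per ray so as to maximize
the summed boundary likeliness

    max  J(p) = sum_i L_i(p_i)      over p in {1..n}^m,

subject to the cyclic smoothness constraints

    |p_1 - p_2| <= s, ..., |p_{m-1} - p_m| <= s, |p_m - p_1| <= s,

with smoothness bound ``s`` (varsigma).  Without the wrap constraint
``|p_m - p_1| <= s`` the problem is a chain and solvable by a standard
Viterbi-style dynamic program in O(nms) time.  The divide & conquer
dynamic program (DCDP) restores the wrap constraint by branch and bound
over contiguous intervals of the admissible values of ``p_m``:

* Solve the *relaxed* problem over ``S_L(I0)`` (wrap constraint dropped,
  ``p_m`` restricted to the interval ``I0`` and ``p_1`` to its
  s-dilation) with one chain DP.
* Rule A (prune): if the relaxed optimum is below the incumbent lower
  bound, no solution in ``S(I0)`` can win.
* Rule B (accept): if the relaxed optimizer already satisfies the wrap
  constraint, it is optimal over ``S(I0)``.
* Rule C (split): otherwise split ``I0`` in two and recurse, passing the
  first branch's bound into the second.

The top-level call ``DCDP({1..n}, -inf)`` returns a global optimum; the
chain DP is invoked at most ``2n - 1`` times.  Three splitting schemes
are provided (``half``, ``max``, ``adap``); an exhaustive dynamic
program (``edp``, one chain DP per endpoint value, always ``n`` calls)
and a brute-force enumerator serve as independent baselines/oracles.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

SCHEMES = ("half", "max", "adap")

_BRUTE_FORCE_LIMIT = 10**7


@dataclass(frozen=True)
class BoundaryProblem:
    """An instance of the cyclic polygon problem.

    Attributes
    ----------
    L : ndarray
        (m, n) table; ``L[i-1, p-1]`` is the boundary likeliness of
        sample ``p`` on ray ``i``.  Any sign, finite.
    varsigma : int
        Smoothness bound (>= 0, default 1).
    """

    L: np.ndarray
    varsigma: int = 1

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        object.__setattr__(self, "L", L)
        if L.ndim != 2 or L.shape[0] < 3 or L.shape[1] < 1:
            raise ValueError("L must be (m>=3, n>=1)")
        if not np.all(np.isfinite(L)):
            raise ValueError("L must be finite")
        if self.varsigma < 0:
            raise ValueError("varsigma must be >= 0")

    @property
    def m(self) -> int:
        return self.L.shape[0]

    @property
    def n(self) -> int:
        return self.L.shape[1]


@dataclass(frozen=True)
class IndexInterval:
    """Contiguous range ``lo..hi`` (inclusive, 1-based) of admissible p_m."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (1 <= self.lo <= self.hi):
            raise ValueError(f"require 1 <= lo <= hi, got [{self.lo}, {self.hi}]")

    @property
    def card(self) -> int:
        return self.hi - self.lo + 1

    def __contains__(self, h: int) -> bool:
        return self.lo <= h <= self.hi


@dataclass(frozen=True)
class PolygonSolution:
    """An index vector with its objective and cyclic feasibility flag."""

    p: np.ndarray
    objective: float
    feasible: bool


@dataclass(frozen=True)
class SolverReport:
    """Result of an exact solver run.

    ``n_dp`` counts invocations of the O(nms) chain-DP routine;
    ``lower_bound`` is the final incumbent bound.
    """

    solution: PolygonSolution
    n_dp: int
    lower_bound: float


def objective(p: np.ndarray, prob: BoundaryProblem) -> float:
    """J(p) = sum_i L_i(p_i)."""
    p = np.asarray(p, dtype=int)
    if p.shape != (prob.m,):
        raise ValueError(f"p must have length m={prob.m}")
    if np.any(p < 1) or np.any(p > prob.n):
        raise ValueError(f"indices must lie in 1..{prob.n}")
    return float(prob.L[np.arange(prob.m), p - 1].sum())


def is_feasible(p: np.ndarray, prob: BoundaryProblem) -> bool:
    """True iff all m cyclic adjacent constraints |p_i - p_{i+1}| <= s hold."""
    p = np.asarray(p, dtype=int)
    diffs = np.abs(np.diff(p, append=p[:1]))
    return bool(np.all(diffs <= prob.varsigma))


def _make_solution(p: np.ndarray, prob: BoundaryProblem) -> PolygonSolution:
    return PolygonSolution(p=np.asarray(p, dtype=int), objective=objective(p, prob),
                           feasible=is_feasible(p, prob))


def solve_chain_dp(prob: BoundaryProblem, I0: IndexInterval) -> PolygonSolution:
    """Maximize J over the relaxed region S_L(I0) (wrap constraint dropped).

    The region is: ``p_m in I0``, ``p_1`` in the s-dilation of I0 clipped
    to ``1..n``, and the chain constraints ``|p_i - p_{i+1}| <= s`` for
    i = 1..m-1.  Backtracking breaks ties toward the smallest index, so
    the result is deterministic.  The returned solution need not satisfy
    the wrap constraint.
    """
    L, s, m, n = prob.L, prob.varsigma, prob.m, prob.n
    if I0.hi > n:
        raise ValueError(f"interval {I0} outside 1..{n}")
    start_lo = max(1, I0.lo - s)
    start_hi = min(n, I0.hi + s)
    if start_lo > start_hi:
        raise ValueError("empty admissible start set")

    neg = -np.inf
    # f[i, p]: best partial objective of p_1..p_{i+1} ending at value p+1 (0-based).
    f = np.full((m, n), neg)
    f[0, start_lo - 1 : start_hi] = L[0, start_lo - 1 : start_hi]
    for i in range(1, m):
        prev = f[i - 1]
        # window max over q in [p-s, p+s]; n is small (<= a few dozen).
        best = np.full(n, neg)
        for d in range(-s, s + 1):
            lo_p, hi_p = max(0, -d), min(n, n - d)
            if lo_p < hi_p:
                seg = prev[lo_p + d : hi_p + d]
                np.maximum(best[lo_p:hi_p], seg, out=best[lo_p:hi_p])
        f[i] = L[i] + best

    # endpoint restricted to I0
    end = f[m - 1, I0.lo - 1 : I0.hi]
    p = np.empty(m, dtype=int)
    p[m - 1] = I0.lo + int(np.argmax(end))  # smallest-index tie-break via argmax
    for i in range(m - 2, -1, -1):
        lo_q = max(1, p[i + 1] - s)
        hi_q = min(n, p[i + 1] + s)
        window = f[i, lo_q - 1 : hi_q]
        p[i] = lo_q + int(np.argmax(window))
    return _make_solution(p, prob)


def split_interval(
    I0: IndexInterval,
    scheme: str,
    prob: BoundaryProblem,
    p_L: np.ndarray | None = None,
    swap: bool = True,
) -> tuple[IndexInterval, IndexInterval]:
    """Split I0 into two non-empty contiguous sub-intervals.

    ``half``
        First half / second half; swap if the best last-ray likeliness in
        I1 is below that in I2 (so the more promising side is explored
        first and its bound prunes the other).
    ``max``
        Split just after ``h* = argmax_{h in I0} L_m(h)``; if the right
        side is empty, ``h*`` moves there; swap if card(I1) > card(I2).
    ``adap``
        Split at the mean of the first and last entries of the current
        relaxed optimizer ``p_L`` (required); empty-side repair and the
        Max-style cardinality swap then apply.

    ``swap=False`` returns the raw division with the exploration-order
    heuristic disabled (the heuristic only affects which side's bound is
    available when the other is pruned, never the optimum).
    """
    if I0.card < 2:
        raise ValueError("cannot split an interval of cardinality < 2")
    Lm = prob.L[-1]
    if scheme == "half":
        cut = I0.lo + I0.card // 2 - 1
        I1 = IndexInterval(I0.lo, cut)
        I2 = IndexInterval(cut + 1, I0.hi)
        if swap and Lm[I1.lo - 1 : I1.hi].max() < Lm[I2.lo - 1 : I2.hi].max():
            I1, I2 = I2, I1
        return I1, I2
    if scheme == "max":
        h_star = I0.lo + int(np.argmax(Lm[I0.lo - 1 : I0.hi]))
        if h_star == I0.hi:  # right side would be empty: move h* across
            I1 = IndexInterval(I0.lo, h_star - 1)
            I2 = IndexInterval(h_star, h_star)
        else:
            I1 = IndexInterval(I0.lo, h_star)
            I2 = IndexInterval(h_star + 1, I0.hi)
        if swap and I1.card > I2.card:
            I1, I2 = I2, I1
        return I1, I2
    if scheme == "adap":
        if p_L is None:
            raise ValueError("adap split requires the current relaxed optimizer")
        cut = (int(p_L[0]) + int(p_L[-1])) / 2.0
        hi1 = int(np.floor(cut))
        hi1 = min(max(hi1, I0.lo - 1), I0.hi)  # clamp before repair
        if hi1 < I0.lo:      # I1 empty: move smallest of I2 into I1
            hi1 = I0.lo
        elif hi1 == I0.hi:   # I2 empty: move largest of I1 into I2
            hi1 = I0.hi - 1
        I1 = IndexInterval(I0.lo, hi1)
        I2 = IndexInterval(hi1 + 1, I0.hi)
        if swap and I1.card > I2.card:
            I1, I2 = I2, I1
        return I1, I2
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def dcdp(
    prob: BoundaryProblem, scheme: str = "adap", *, prune: bool = True
) -> SolverReport:
    """Solve the cyclic problem exactly by divide & conquer branch and bound.

    Parameters
    ----------
    prob : BoundaryProblem
    scheme : {'half', 'max', 'adap'}
        Splitting scheme used in Rule C.
    prune : bool
        Disable to skip Rule A (useful only to audit pruning soundness;
        the result is unchanged).

    Returns
    -------
    SolverReport
        Globally optimal, cyclically feasible solution; ``n_dp`` counts
        chain-DP invocations (at most ``2n - 1``).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    counter = {"n_dp": 0}

    def recurse(I0: IndexInterval, lb: float):
        counter["n_dp"] += 1
        sol_L = solve_chain_dp(prob, I0)
        # Rule A: prune
        if prune and sol_L.objective < lb:
            return None, -np.inf, lb
        # Rule B: relaxed optimizer already cyclically feasible -> accept
        if abs(int(sol_L.p[-1]) - int(sol_L.p[0])) <= prob.varsigma:
            return sol_L, sol_L.objective, sol_L.objective
        # Rule C: split and recurse, threading the bound
        I1, I2 = split_interval(I0, scheme, prob, sol_L.p)
        p1, J1, l1 = recurse(I1, lb)
        p2, J2, l2 = recurse(I2, l1)
        if J2 > J1:
            return p2, J2, max(l1, l2)
        return p1, J1, max(l1, l2)

    sol, J, lb = recurse(IndexInterval(1, prob.n), -np.inf)
    assert sol is not None and sol.feasible
    return SolverReport(solution=sol, n_dp=counter["n_dp"], lower_bound=lb)


def edp(prob: BoundaryProblem) -> SolverReport:
    """Exhaustive dynamic program: one chain DP per endpoint value.

    Sub-problem ``h`` fixes ``p_m = h`` and allows ``p_1`` within
    ``[h - s, h + s]``, so the wrap constraint holds by construction;
    the best of the ``n`` sub-problem optima is a global optimum.
    ``n_dp`` is always ``n``.
    """
    best: PolygonSolution | None = None
    for h in range(1, prob.n + 1):
        sol = solve_chain_dp(prob, IndexInterval(h, h))
        if best is None or sol.objective > best.objective:
            best = sol
    assert best is not None and best.feasible
    return SolverReport(solution=best, n_dp=prob.n, lower_bound=best.objective)


def brute_force(prob: BoundaryProblem) -> PolygonSolution:
    """Exhaustively enumerate {1..n}^m (test oracle; guarded to n^m <= 1e7).

    Ties are broken lexicographically (the first maximizer in
    lexicographic order wins), making the result deterministic.
    """
    m, n, s = prob.m, prob.n, prob.varsigma
    if n**m > _BRUTE_FORCE_LIMIT:
        raise ValueError(f"instance too large for brute force: n^m > {_BRUTE_FORCE_LIMIT}")
    # all n^m candidates in lexicographic row order (vectorized enumeration)
    grids = np.meshgrid(*(np.arange(1, n + 1, dtype=np.int16),) * m, indexing="ij")
    cands = np.stack(grids, axis=-1).reshape(-1, m)
    diffs = np.abs(cands - np.roll(cands, -1, axis=1))
    feasible = np.all(diffs <= s, axis=1)
    if not feasible.any():
        raise RuntimeError("no feasible solution (unreachable for varsigma >= 0)")
    J = prob.L[np.arange(m), cands - 1].sum(axis=1)
    J[~feasible] = -np.inf
    best = int(np.argmax(J))  # first maximizer = lexicographically smallest
    return _make_solution(cands[best].astype(int), prob)
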