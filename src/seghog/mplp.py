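"""MPLP block coordinate descent on the LP-relaxation dual (baseline solver).

The cyclic polygon problem is a MAP problem on a cycle-structured Markov
random field: node potentials ``L_i`` and hard pairwise constraints
``|p_i - p_{i+1}| <= s`` on each of the ``m`` edges (edge ``m`` closes
the cycle).  MPLP minimizes the dual of the LP relaxation,

    Psi(lam) = sum_i max_p ( L_i(p) + lam(p, i, i) + lam(p, i-1, i) )
             - sum_i min_{|p - q| <= s} ( lam(p, i, i) + lam(q, i, i+1) ),

where ``lam(p, i, i)`` is the message from edge ``(i, i+1)`` to node
``i`` and ``lam(q, i, i+1)`` the message from the same edge to node
``i + 1`` (indices wrap: ``lam(., 0, 1) == lam(., m, 1)``).  Each block
coordinate step re-optimizes the two message vectors of one edge given
all other messages:

    lam(p, i, i)     := -1/2 (L_i(p) + lam(p, i-1, i))
                        + 1/2 max_{|q-p|<=s} ( L_{i+1}(q) + lam(q, i+1, i+1) )
    lam(q, i, i+1)   := -1/2 (L_{i+1}(q) + lam(q, i+1, i+1))
                        + 1/2 max_{|p-q|<=s} ( L_i(p) + lam(p, i-1, i) )

which only reads messages owned by the neighbouring edges, so each step
is an exact block minimization and Psi never increases.  Plain MPLP
sweeps the edges sequentially; MPLP+ updates all odd-numbered edges
simultaneously and then all even-numbered ones (valid because, for a
cycle with even ``m``, odd edges share no Psi term with each other).
Weak duality gives ``Psi(lam) >= max J`` at every iterate, so a decoded
primal that closes the gap is certifiably optimal.  Convergence to the
optimum is not guaranteed (the LP relaxation of a cycle can be loose);
the exact DCDP solver is the reference this baseline is compared with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import BoundaryProblem, PolygonSolution, is_feasible, objective

MODES = ("mplp", "mplp_plus")


@dataclass
class DualVariables:
    """Messages of all m edges.

    ``node[i-1, p-1]`` is lam(p, i, i) (edge (i, i+1) -> node i) and
    ``edge[i-1, p-1]`` is lam(p, i, i+1) (edge (i, i+1) -> node i+1);
    row m wraps to node 1.
    """

    node: np.ndarray
    edge: np.ndarray

    @classmethod
    def zeros(cls, prob: BoundaryProblem) -> "DualVariables":
        return cls(node=np.zeros((prob.m, prob.n)), edge=np.zeros((prob.m, prob.n)))

    def copy(self) -> "DualVariables":
        return DualVariables(node=self.node.copy(), edge=self.edge.copy())


def _window_max(values: np.ndarray, s: int) -> np.ndarray:
    """out[p] = max_{|q - p| <= s} values[q] (indices clipped to range)."""
    n = values.shape[-1]
    out = np.full_like(values, -np.inf)
    for d in range(-s, s + 1):
        lo, hi = max(0, -d), min(n, n - d)
        if lo < hi:
            np.maximum(out[..., lo:hi], values[..., lo + d : hi + d],
                       out=out[..., lo:hi])
    return out


def _node_beliefs(prob: BoundaryProblem, lam: DualVariables) -> np.ndarray:
    """b[i-1, p-1] = L_i(p) + lam(p, i, i) + lam(p, i-1, i)."""
    incoming_prev = np.roll(lam.edge, 1, axis=0)  # lam(., i-1, i); row 0 <- edge m
    return prob.L + lam.node + incoming_prev


def dual_objective(prob: BoundaryProblem, lam: DualVariables) -> float:
    """Psi(lam), an upper bound on the optimal J (weak duality)."""
    if lam.node.shape != prob.L.shape or lam.edge.shape != prob.L.shape:
        raise ValueError("dual variable shape does not match the problem")
    node_term = _node_beliefs(prob, lam).max(axis=1).sum()
    # min over s-compatible pairs of lam(p,i,i) + lam(q,i,i+1)
    pair_min = (-_window_max(-lam.edge, prob.varsigma) + lam.node).min(axis=1)
    return float(node_term - pair_min.sum())


def _update_edge_block(prob: BoundaryProblem, lam: DualVariables, i: int) -> None:
    """Re-optimize the two message vectors of edge (i, i+1) in place.

    ``i`` is 0-based here; reads only messages of edges i-1 and i+1.
    """
    s = prob.varsigma
    j = (i + 1) % prob.m
    # messages into the two endpoint nodes from *outside* this edge block
    into_i = prob.L[i] + lam.edge[i - 1]      # L_i + lam(., i-1, i)
    into_j = prob.L[j] + lam.node[j]          # L_{i+1} + lam(., i+1, i+1)
    lam.node[i] = -0.5 * into_i + 0.5 * _window_max(into_j, s)
    lam.edge[i] = -0.5 * into_j + 0.5 * _window_max(into_i, s)


def mplp_iterate(prob: BoundaryProblem, lam: DualVariables, mode: str = "mplp") -> DualVariables:
    """One full pass over all m edge blocks; returns the updated duals.

    ``mplp`` sweeps edges 1..m sequentially.  ``mplp_plus`` updates all
    odd-numbered edges simultaneously, then all even-numbered ones (for
    odd ``m``, edge ``m`` joins the odd group).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    lam = lam.copy()
    m = prob.m
    if mode == "mplp":
        for i in range(m):
            _update_edge_block(prob, lam, i)
    else:
        odd = list(range(0, m, 2))          # edges 1, 3, ... (1-based)
        even = list(range(1, m, 2))
        if m % 2 == 1:                       # edge m joins the odd block
            pass                             # range(0, m, 2) already includes m-1
        for group in (odd, even):
            snapshot = lam.copy()
            for i in group:
                # read from the pre-group snapshot, write into lam
                s = prob.varsigma
                j = (i + 1) % m
                into_i = prob.L[i] + snapshot.edge[i - 1]
                into_j = prob.L[j] + snapshot.node[j]
                lam.node[i] = -0.5 * into_i + 0.5 * _window_max(into_j, s)
                lam.edge[i] = -0.5 * into_j + 0.5 * _window_max(into_i, s)
    return lam


def decode_primal(prob: BoundaryProblem, lam: DualVariables) -> PolygonSolution:
    """Decode p_i = argmax_p (L_i(p) + lam(p,i,i) + lam(p,i-1,i)).

    Ties break toward the smallest index.  The decoded vector may violate
    the cyclic constraints; its ``feasible`` flag records the check.
    """
    p = np.argmax(_node_beliefs(prob, lam), axis=1) + 1
    return PolygonSolution(p=p, objective=objective(p, prob),
                           feasible=is_feasible(p, prob))


@dataclass(frozen=True)
class MplpResult:
    solution: PolygonSolution
    dual_value: float
    iterations: int
    converged: bool


def mplp_solve(
    prob: BoundaryProblem,
    mode: str = "mplp",
    max_iters: int = 10000,
    tol: float = 1e-9,
) -> MplpResult:
    """Run MPLP until the decoded primal certifies optimality or max_iters.

    Convergence means the decoded primal is cyclically feasible and the
    duality gap ``Psi - J(p)`` is at most ``tol``.  On non-convergence the
    best feasible decode seen is returned with ``converged=False`` (no
    exception).
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    lam = DualVariables.zeros(prob)
    best: PolygonSolution | None = None
    for it in range(1, max_iters + 1):
        lam = mplp_iterate(prob, lam, mode)
        psi = dual_objective(prob, lam)
        sol = decode_primal(prob, lam)
        if sol.feasible and (best is None or sol.objective > best.objective):
            best = sol
        if sol.feasible and psi - sol.objective <= tol:
            return MplpResult(solution=sol, dual_value=psi, iterations=it, converged=True)
    if best is None:
        best = decode_primal(prob, lam)
    return MplpResult(solution=best, dual_value=dual_objective(prob, lam),
                      iterations=max_iters, converged=False)
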