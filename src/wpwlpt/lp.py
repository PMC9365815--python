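"""The maximin linear program that fits the weighted Parzen window.

Given distinct gray levels g_1..g_k with kernel widths sigma_1..sigma_k,
the mixture weights a and the coverage level rho solve

    max  rho
    s.t. sum_i a_i = 1
         sum_i a_i phi(g_j; g_i, sigma_i) >= rho   for every j
         a_i >= 0

so that the fitted mixture p_hat(g) = sum_i a_i phi(g; g_i, sigma_i)
covers every observed gray level at height at least rho, and rho — the
guaranteed minimum coverage — is as large as possible.  The level set
p_hat = rho then delineates the boundary of the gray-value distribution.

Although the underlying samples are all N pixels, pixels sharing a gray
value produce identical covering constraints and interchangeable weights,
so the program is posed over the <= 256 distinct levels.  This collapse is
exact, not an approximation; multiplicities enter only through the kernel
widths.

The program always has an optimum: a = e_1 with rho = min_j K[j, 1] is
feasible, and the constraints bound rho by the largest kernel peak.

Because rho* > 0 (the kernel matrix is elementwise positive on its
diagonal), the program is exactly the linear program of a matrix game with
payoff matrix K: substituting u = a / rho turns it into
``min 1'u : K u >= 1, u >= 0`` with rho* = 1 / sum(u).  The solver runs a
dense primal simplex on that problem's dual, ``max 1'v : K' v <= 1,
v >= 0``, whose slack basis is immediately feasible with a strictly
positive right-hand side — no artificial phase, and far less degeneracy
than the direct formulation (whose right-hand side is almost entirely
zero).  The optimal weights a are recovered from the dual multipliers and
certified against the original constraints.  Pivoting is deterministic:
largest-coefficient (Dantzig) entering rule, switching permanently to
Bland's smallest-index rule after a run of degenerate pivots so that
cycling is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np

from .parzen import KernelSpec, kernel_eval

__all__ = [
    "WeightedWindowLP",
    "LPSolution",
    "build_lp",
    "feasible_start",
    "solve_simplex",
    "validate_solution",
    "dump_lp",
    "load_lp",
]


@dataclass(frozen=True)
class WeightedWindowLP:
    """Maximin coverage LP over distinct gray levels.

    kernel_matrix[j, i] = phi(g_j; g_i, sigma_i); variables are the k
    simplex weights a plus the level rho.
    """

    levels: np.ndarray  # distinct gray values g_i, shape (k,)
    widths: np.ndarray  # per-level kernel widths sigma_i, shape (k,)
    kernel_matrix: np.ndarray  # shape (k, k)
    dim: int = 1

    @property
    def n_samples(self) -> int:
        return int(self.levels.size)

    @property
    def peak_max(self) -> float:
        """Upper bound on rho: the largest kernel peak, (sqrt(2 pi) sigma_min)^-d."""
        return kernel_eval(0.0, 0.0, float(self.widths.min()), self.dim)


@dataclass(frozen=True)
class LPSolution:
    weights: np.ndarray  # a, shape (k,)
    rho: float
    objective: float
    status: str  # "optimal" | "feasible" | "infeasible" | "iteration-limit"
    iterations: int
    support_tol: float = 1e-9

    @property
    def support(self) -> np.ndarray:
        """Active kernel centres: indices with a_i > support_tol."""
        return np.flatnonzero(self.weights > self.support_tol)


def build_lp(
    present_levels: Sequence[int] | np.ndarray,
    widths: Sequence[float] | np.ndarray,
    spec: KernelSpec = KernelSpec(),
) -> WeightedWindowLP:
    """Assemble the kernel matrix and constraint data for the coverage LP."""
    levels = np.asarray(present_levels, dtype=np.float64)
    widths = np.asarray(widths, dtype=np.float64)
    if levels.size == 0:
        raise ValueError("at least one gray level is required")
    if levels.shape != widths.shape:
        raise ValueError("levels and widths must have equal length")
    if np.any(widths <= 0):
        raise ValueError("widths must be > 0")
    # K[j, i] = phi(g_j; g_i, sigma_i): column i carries centre i's width.
    diff = levels[:, None] - levels[None, :]
    norm = (np.sqrt(2.0 * np.pi) * widths) ** (-spec.dim)
    K = norm[None, :] * np.exp(-(diff**2) / (2.0 * widths[None, :] ** 2))
    return WeightedWindowLP(
        levels=levels, widths=widths, kernel_matrix=K, dim=spec.dim
    )


def feasible_start(lp: WeightedWindowLP) -> LPSolution:
    """The always-feasible point: all weight on the first sample.

    a = e_1 satisfies the simplex constraints, and rho = min_j K[j, 1]
    makes every covering constraint hold with equality at the worst row.
    """
    k = lp.n_samples
    a = np.zeros(k)
    a[0] = 1.0
    rho = float(lp.kernel_matrix[:, 0].min())
    return LPSolution(weights=a, rho=rho, objective=rho, status="feasible", iterations=0)


# ---------------------------------------------------------------------------
# dense primal simplex on the game-dual form
# ---------------------------------------------------------------------------

_PIVOT_TOL = 1e-9
_STALL_LIMIT = 100  # degenerate pivots tolerated before switching to Bland


def _simplex_max(
    A: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    tol: float,
    maxiter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, str]:
    """Primal simplex for ``max c'x : A x <= b, x >= 0`` with b > 0.

    Dense tableau with the slack basis as the start.  Entering variable by
    Dantzig's largest-coefficient rule; after ``_STALL_LIMIT`` consecutive
    degenerate pivots the rule switches permanently to Bland's
    smallest-index rule, which rules out cycling.  Leaving variable by the
    minimum-ratio test, ties broken toward the smallest basic index.

    Returns (x, y, reduced_costs, iterations, status) where y are the dual
    multipliers of the rows.
    """
    m, n_struct = A.shape
    n = n_struct + m
    T = np.hstack([A, np.eye(m), b[:, None]])
    cost = np.concatenate([c, np.zeros(m)])
    basis = np.arange(n_struct, n)
    status = "iteration-limit"
    bland = False
    stall = 0
    it = 0
    for it in range(1, maxiter + 1):
        r = cost[basis] @ T[:, :n] - cost  # >= 0 everywhere at the optimum
        if bland:
            neg = np.flatnonzero(r < -tol)
            if neg.size == 0:
                status = "optimal"
                break
            entering = int(neg[0])
        else:
            entering = int(np.argmin(r))
            if r[entering] >= -tol:
                status = "optimal"
                break
        col = T[:, entering]
        rows = np.flatnonzero(col > tol)
        if rows.size == 0:
            status = "unbounded"
            break
        ratios = T[rows, n] / col[rows]
        best = float(ratios.min())
        tie = rows[ratios <= best + tol * (1.0 + abs(best))]
        leave = int(tie[np.argmin(basis[tie])])
        T[leave] /= T[leave, entering]
        piv_row = T[leave].copy()
        factor = T[:, entering].copy()
        factor[leave] = 0.0
        T -= np.outer(factor, piv_row)
        T[leave] = piv_row
        basis[leave] = entering
        if best <= tol:
            stall += 1
            if stall > _STALL_LIMIT:
                bland = True
        else:
            stall = 0
    x = np.zeros(n)
    x[basis] = T[:, n]
    r = cost[basis] @ T[:, :n] - cost
    y = r[n_struct:]  # duals = reduced costs of the slack columns
    return x[:n_struct], y, r, it, status


def solve_simplex(
    lp: WeightedWindowLP, tol: float = _PIVOT_TOL, maxiter: int | None = None
) -> LPSolution:
    """Solve the coverage LP to optimality.

    The simplex runs on the equivalent game-dual program
    ``max 1'v : K' v <= 1, v >= 0`` (see the module docstring); the
    weights are the normalized dual multipliers a = y / sum(y) and the
    optimal level is rho* = 1 / sum(y).  The returned vertex is
    deterministic for a fixed instance.
    """
    k = lp.n_samples
    K = lp.kernel_matrix
    if maxiter is None:
        maxiter = 500 * k + 2000
    _, y, _, iters, status = _simplex_max(
        K.T.copy(), np.ones(k), np.ones(k), tol, maxiter
    )
    if status != "optimal":
        return LPSolution(
            weights=np.zeros(k),
            rho=0.0,
            objective=0.0,
            status="iteration-limit",
            iterations=iters,
        )
    y = np.clip(y, 0.0, None)
    total = float(y.sum())
    a = y / total
    rho = 1.0 / total
    return LPSolution(weights=a, rho=rho, objective=rho, status=status, iterations=iters)


def validate_solution(
    lp: WeightedWindowLP, sol: LPSolution, tol: float = 1e-7
) -> dict[str, bool]:
    """Feasibility and optimality certificates for one solution.

    Checks the simplex constraint, nonnegativity, every covering
    constraint, tightness of the binding constraint (min_j (K a)_j = rho at
    an optimum), and the analytic bounds 0 <= rho <= peak_max.
    """
    a = sol.weights
    cover = lp.kernel_matrix @ a
    checks = {
        "sum_to_one": bool(abs(float(a.sum()) - 1.0) <= tol),
        "nonnegative": bool(np.all(a >= -tol)),
        "covering": bool(np.all(cover >= sol.rho - tol)),
        "rho_bounds": bool(-tol <= sol.rho <= lp.peak_max + tol),
    }
    if sol.status == "optimal":
        checks["binding"] = bool(abs(float(cover.min()) - sol.rho) <= tol)
    checks["all"] = all(checks.values())
    return checks


# ---------------------------------------------------------------------------
# plain-text instance round-trip (debugging / oracle cross-checks)
# ---------------------------------------------------------------------------


def dump_lp(lp: WeightedWindowLP, fh: TextIO) -> None:
    """Write an instance as plain text: header, levels, widths, matrix rows."""
    fh.write(f"wpwlpt-lp 1 {lp.n_samples} {lp.dim}\n")
    fh.write(" ".join(repr(float(v)) for v in lp.levels) + "\n")
    fh.write(" ".join(repr(float(v)) for v in lp.widths) + "\n")
    for row in lp.kernel_matrix:
        fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def load_lp(fh: TextIO) -> WeightedWindowLP:
    header = fh.readline().split()
    if len(header) != 4 or header[0] != "wpwlpt-lp":
        raise ValueError("not a wpwlpt LP dump")
    k, dim = int(header[2]), int(header[3])
    levels = np.array([float(v) for v in fh.readline().split()])
    widths = np.array([float(v) for v in fh.readline().split()])
    rows = [[float(v) for v in fh.readline().split()] for _ in range(k)]
    K = np.array(rows)
    if levels.size != k or widths.size != k or K.shape != (k, k):
        raise ValueError("malformed LP dump")
    return WeightedWindowLP(levels=levels, widths=widths, kernel_matrix=K, dim=dim)
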