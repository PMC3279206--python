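"""Sparse recovery of a spectrum against a training dictionary.

The classifier needs, for a pixel spectrum ``y`` and dictionary ``A``
with unit-norm columns, a sparse coefficient vector solving

    min ||g||_1   subject to  ||y - A g||_2 <= eps        (basis pursuit)

or its greedy surrogate (orthogonal matching pursuit), standing in for
the NP-hard l0 problem.  Three routes are provided:

* :func:`solve_greedy` — OMP: pick the atom most correlated with the
  current residual, re-fit least squares on the support, repeat.  The
  pipeline default (fast, and adequate for very small supports).
* :func:`solve_basis_pursuit` — the convex l1 program.  For (near-)exact
  representation it is solved as the classical linear program
  ``min 1'(u+v) s.t. A(u-v)=y, u,v>=0``; for a positive noise tolerance
  it is solved through the equivalent penalized lasso, bisecting the
  penalty until the residual meets the tolerance.
* :func:`brute_force_l0` — exhaustive support enumeration; the ground
  truth oracle for testing, never used in the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .errors import BudgetError, InfeasibleError, ParameterError, SolverError

__all__ = [
    "SolverConfig",
    "Coefficients",
    "solve_basis_pursuit",
    "solve_greedy",
    "brute_force_l0",
    "solve",
]

#: coefficients below this magnitude are treated as numerical zeros
SUPPORT_THRESHOLD = 1e-10


@dataclass
class SolverConfig:
    """Sparse-solver settings.

    eps
        Absolute error tolerance (the epsilon of the reconstruction
        constraint).  ``None`` means derive it per call as
        ``eps_rel * ||y||_2``.
    eps_rel
        Relative tolerance used when ``eps`` is None.  Reflectance noise
        scales with signal, so a relative default (0.05) transfers
        across scenes where an absolute one would not.
    max_atoms
        Sparsity cap for the greedy solver; a handful of training pixels
        suffices to span a tissue subspace.
    tol_lstsq
        Cutoff ratio for small singular values in the inner least-squares
        refits.
    """

    method: str = "greedy"
    eps: Optional[float] = None
    eps_rel: float = 0.05
    max_atoms: int = 10
    tol_lstsq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method not in ("greedy", "basis_pursuit"):
            raise ParameterError(f"unknown solver method {self.method!r}")
        if self.eps is not None and self.eps < 0:
            raise ParameterError("eps must be >= 0")
        if self.eps is None and self.eps_rel < 0:
            raise ParameterError("eps_rel must be >= 0")
        if self.max_atoms < 1:
            raise ParameterError("max_atoms must be a positive integer")

    def effective_eps(self, y: np.ndarray) -> float:
        return float(self.eps) if self.eps is not None \
            else float(self.eps_rel * np.linalg.norm(y))


@dataclass
class Coefficients:
    """A recovered coefficient vector with its support and residual norm."""

    values: np.ndarray
    residual_norm: float
    support: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.support = np.flatnonzero(np.abs(self.values) > SUPPORT_THRESHOLD)
        if self.residual_norm < 0:
            raise ParameterError("residual norm cannot be negative")


def _check_problem(y: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != y.size or min(a.shape) < 1:
        raise ParameterError(f"incompatible shapes y{y.shape} A{a.shape}")
    return y, a


def _lstsq_on(y: np.ndarray, a: np.ndarray, support, n: int,
              rcond: Optional[float]) -> tuple[np.ndarray, float]:
    """Least-squares fit restricted to *support*; returns (gamma, residual)."""
    gamma = np.zeros(n)
    if len(support) == 0:
        return gamma, float(np.linalg.norm(y))
    sol, *_ = np.linalg.lstsq(a[:, list(support)], y, rcond=rcond)
    gamma[list(support)] = sol
    return gamma, float(np.linalg.norm(y - a @ gamma))


# ---------------------------------------------------------------------------
# greedy pursuit (OMP)
# ---------------------------------------------------------------------------

def solve_greedy(y: np.ndarray, a: np.ndarray, cfg: SolverConfig) -> Coefficients:
    """Orthogonal matching pursuit.

    At each step the atom with maximal absolute correlation with the
    current residual joins the support, and the coefficients are re-fit
    by least squares on the support.  Stops when the residual norm drops
    to ``eps``, when ``max_atoms`` atoms are active, when the residual is
    orthogonal to every atom, or when an iteration fails to decrease the
    residual.  Residual norms are non-increasing across iterations.
    """
    y, a = _check_problem(y, a)
    n = a.shape[1]
    eps = cfg.effective_eps(y)
    max_atoms = min(cfg.max_atoms, n)
    support: list[int] = []
    gamma = np.zeros(n)
    residual = y.copy()
    res_norm = float(np.linalg.norm(y))
    while res_norm > eps and len(support) < max_atoms:
        corr = np.abs(a.T @ residual)
        if support:
            corr[support] = -np.inf
        j = int(np.argmax(corr))
        if corr[j] <= SUPPORT_THRESHOLD * max(1.0, res_norm):
            break  # residual orthogonal to all remaining atoms
        trial_support = support + [j]
        trial_gamma, trial_norm = _lstsq_on(y, a, trial_support, n, cfg.tol_lstsq)
        if trial_norm >= res_norm - 1e-14 * max(1.0, res_norm):
            break  # no progress: terminate rather than loop
        support, gamma, res_norm = trial_support, trial_gamma, trial_norm
        residual = y - a @ gamma
    return Coefficients(gamma, res_norm)


# ---------------------------------------------------------------------------
# basis pursuit
# ---------------------------------------------------------------------------

def _bp_equality(y: np.ndarray, a: np.ndarray) -> np.ndarray:
    """min ||g||_1 s.t. A g = y, as the LP min 1'(u+v), g = u - v."""
    b, n = a.shape
    c = np.ones(2 * n)
    a_eq = np.hstack([a, -a])
    res = linprog(c, A_eq=a_eq, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:
        raise SolverError(
            f"basis-pursuit LP failed: {res.message} (status {res.status})"
        )
    uv = res.x
    return uv[:n] - uv[n:]


def _lasso_fit(y: np.ndarray, a: np.ndarray, alpha: float) -> np.ndarray:
    from sklearn.linear_model import Lasso

    model = Lasso(alpha=alpha, fit_intercept=False, tol=1e-14,
                  max_iter=200_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter at tiny alpha
        model.fit(a, y)
    return model.coef_.astype(float)


def _bp_denoise(y: np.ndarray, a: np.ndarray, eps: float) -> np.ndarray:
    """Noise-tolerant basis pursuit via the lasso path.

    The constrained program and the penalized lasso share solutions: the
    lasso residual norm increases monotonically with the penalty, so the
    penalty meeting ``residual == eps`` yields the l1-minimal feasible
    point.  Located by bisection.
    """
    b = y.size
    # penalty above which the lasso solution is exactly zero
    alpha_hi = float(np.max(np.abs(a.T @ y))) / b
    if alpha_hi == 0.0:
        return np.zeros(a.shape[1])
    alpha_lo = alpha_hi
    for _ in range(60):
        alpha_lo /= 4.0
        g = _lasso_fit(y, a, alpha_lo)
        if np.linalg.norm(y - a @ g) <= eps:
            break
    else:
        raise SolverError("lasso bisection: could not bracket the tolerance")
    g_best = g
    for _ in range(80):
        mid = 0.5 * (alpha_lo + alpha_hi)
        g = _lasso_fit(y, a, mid)
        if np.linalg.norm(y - a @ g) <= eps:
            alpha_lo, g_best = mid, g
        else:
            alpha_hi = mid
        if (alpha_hi - alpha_lo) <= 1e-12 * alpha_hi:
            break
    return g_best


def solve_basis_pursuit(y: np.ndarray, a: np.ndarray,
                        cfg: SolverConfig) -> Coefficients:
    """l1-minimal coefficients subject to ``||y - A g||_2 <= eps``.

    ``eps = 0`` reproduces the equality-constrained program.  Raises
    :class:`InfeasibleError` when even the unconstrained least-squares
    fit cannot reach the tolerance.
    """
    y, a = _check_problem(y, a)
    eps = cfg.effective_eps(y)
    y_norm = float(np.linalg.norm(y))
    if y_norm <= eps:
        return Coefficients(np.zeros(a.shape[1]), y_norm)
    _, min_res = _lstsq_on(y, a, range(a.shape[1]), a.shape[1], cfg.tol_lstsq)
    if min_res > eps + 1e-8 * max(1.0, y_norm):
        raise InfeasibleError(
            f"tolerance eps={eps:g} unreachable (least-squares residual "
            f"{min_res:g})"
        )
    # at (near-)zero tolerance the equality LP is exact and vertex-sparse
    if eps <= max(min_res, 1e-7 * y_norm):
        gamma = _bp_equality(y, a)
    else:
        gamma = _bp_denoise(y, a, eps)
    gamma[np.abs(gamma) <= SUPPORT_THRESHOLD] = 0.0
    return Coefficients(gamma, float(np.linalg.norm(y - a @ gamma)))


# ---------------------------------------------------------------------------
# exhaustive l0 oracle (testing only)
# ---------------------------------------------------------------------------

def brute_force_l0(y: np.ndarray, a: np.ndarray, max_k: int,
                   budget: int = 1_000_000) -> Coefficients:
    """Exhaustive search over all supports of size 0..max_k.

    Returns the sparsest support attaining (within 1e-9 relative) the
    globally minimal residual; ties broken by smaller residual, then by
    lexicographically smallest support.  Strictly a test oracle — the
    enumeration cost is combinatorial and guarded by *budget*.
    """
    y, a = _check_problem(y, a)
    n = a.shape[1]
    max_k = min(max_k, n)
    total = sum(comb(n, k) for k in range(max_k + 1))
    if total > budget:
        raise BudgetError(
            f"enumerating {total} supports exceeds the budget of {budget}"
        )
    best_per_size: list[tuple[float, tuple[int, ...]]] = []
    for k in range(max_k + 1):
        best_res, best_sup = np.inf, ()
        for sup in combinations(range(n), k):
            _, res = _lstsq_on(y, a, sup, n, None)
            if res < best_res - 1e-15:  # lex order: keep first at equal residual
                best_res, best_sup = res, sup
        best_per_size.append((best_res, best_sup))
    global_min = min(res for res, _ in best_per_size)
    tol = 1e-9 * max(1.0, float(np.linalg.norm(y)))
    for res, sup in best_per_size:  # smallest size reaching the optimum wins
        if res <= global_min + tol:
            gamma, res_exact = _lstsq_on(y, a, sup, n, None)
            return Coefficients(gamma, res_exact)
    raise SolverError("unreachable: no support met its own minimum")


def solve(y: np.ndarray, a: np.ndarray, cfg: SolverConfig) -> Coefficients:
    """Dispatch to the solver selected by ``cfg.method``."""
    if cfg.method == "greedy":
        return solve_greedy(y, a, cfg)
    return solve_basis_pursuit(y, a, cfg)
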