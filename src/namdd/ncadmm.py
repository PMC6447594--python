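"""Nonconvex ADMM solver for sparse-plus-group-sparse multivariate regression.

The model regresses Q gene-expression traits on P methylation sites jointly:

    min_B  1/2 ||X B - Y||_F^2 + alpha ||B||_1 + beta * sum_i ||b^i||_2

The elementwise L1 term makes individual site-gene coefficients sparse; the
row-group term zeroes whole rows of B, so only a few sites influence any gene
at all.  Variable splitting introduces a proxy W for B and a dual matrix
Lambda, and each penalty is applied through a generalized p-shrinkage map
with exponent u <= 1 (u = 1 is the classical soft threshold; u < 1 shrinks
large coefficients less aggressively while thresholding small ones harder,
the nonconvex regime this solver exists for).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .core_io import ConvergenceError, ValidationError

__all__ = [
    "SolverSettings",
    "CoefficientState",
    "p_shrink",
    "group_shrink",
    "update_B",
    "update_W",
    "solve_ncadmm",
]


@dataclass
class SolverSettings:
    """Penalty weights and iteration controls for one ADMM solve."""

    alpha: float = 0.1
    beta: float = 0.1
    u: float = 0.5
    v: float = 0.5
    max_iter: int = 500
    tol: float = 1e-6
    rho: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("alpha and beta must be >= 0")
        if self.u > 1 or self.v > 1:
            raise ValidationError("shrinkage exponents must be <= 1")
        if self.tol <= 0 or self.rho <= 0:
            raise ValidationError("tol and rho must be > 0")


@dataclass
class CoefficientState:
    """ADMM iterate: coefficients B, proxy W, dual Lambda (all P x Q).

    At declared convergence max|W - B| <= tol, so the support of W (the
    thresholded proxy) is the set of detected methylation-gene edges.
    """

    B: np.ndarray
    W: np.ndarray
    Lambda: np.ndarray
    n_iter: int = 0
    converged: bool = False
    primal_residual: float = np.inf


def p_shrink(b: np.ndarray, alpha: float, u: float) -> np.ndarray:
    """Elementwise p-shrinkage  sign(b) * max{0, |b| - alpha^(2-u) |b|^(u-1)}.

    With u = 1 this is soft thresholding at alpha.  Zero entries map to zero
    (the max{0, .} guard makes the 0^(u-1) singularity irrelevant).
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    b = np.asarray(b, dtype=float)
    if alpha == 0:
        return b.copy()
    absb = np.abs(b)
    out = np.zeros_like(b)
    nz = absb > 0
    if u == 1.0:
        thresh = alpha  # exact soft threshold
    else:
        # log-space product avoids spurious 0*inf when alpha^(2-u)
        # underflows while |b|^(u-1) overflows (or vice versa)
        with np.errstate(over="ignore"):
            thresh = np.exp((2.0 - u) * np.log(alpha) + (u - 1.0) * np.log(absb[nz]))
    out[nz] = np.sign(b[nz]) * np.maximum(0.0, absb[nz] - thresh)
    return out


def group_shrink(b: np.ndarray, alpha: float, u: float) -> np.ndarray:
    """Group p-shrinkage: scale b by max{0, ||b|| - alpha^(2-u) ||b||^(u-1)} / ||b||.

    The zero vector maps to itself; otherwise the output is a nonnegative
    multiple of the input, so directions are preserved.
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    b = np.asarray(b, dtype=float)
    if alpha == 0:
        return b.copy()
    nrm = float(np.linalg.norm(b))
    if nrm == 0.0:
        return np.zeros_like(b)
    if u == 1.0:
        thresh = alpha
    else:
        with np.errstate(over="ignore"):
            thresh = np.exp((2.0 - u) * np.log(alpha) + (u - 1.0) * np.log(nrm))
    factor = max(0.0, nrm - thresh) / nrm
    return b * factor


def _shrink_rows(M: np.ndarray, alpha: float, u: float) -> np.ndarray:
    """Apply group_shrink to every row of M (vectorized)."""
    if alpha == 0:
        return M.copy()
    norms = np.linalg.norm(M, axis=1)
    factors = np.zeros_like(norms)
    nz = norms > 0
    if u == 1.0:
        thresh = alpha
    else:
        with np.errstate(over="ignore"):
            thresh = np.exp((2.0 - u) * np.log(alpha) + (u - 1.0) * np.log(norms[nz]))
    factors[nz] = np.maximum(0.0, norms[nz] - thresh) / norms[nz]
    return M * factors[:, None]


def update_B(
    state: CoefficientState,
    X: np.ndarray,
    Y: np.ndarray,
    settings: SolverSettings,
    cho: tuple | None = None,
) -> np.ndarray:
    """B-subproblem: minimize 1/2||XB - Y||_F^2 + rho/2 ||W - B - Lambda||_F^2.

    Closed form: (X'X + rho I) B = X'Y + rho (W - Lambda).  A pre-computed
    Cholesky factor of the left-hand side may be supplied and is reused
    across iterations.
    """
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValidationError("X and Y must be finite")
    rho = settings.rho
    rhs = X.T @ Y + rho * (state.W - state.Lambda)
    if cho is None:
        A = X.T @ X + rho * np.eye(X.shape[1])
        cho = cho_factor(A)
    return cho_solve(cho, rhs)


def update_W(state: CoefficientState, settings: SolverSettings) -> np.ndarray:
    """W-subproblem: penalized proximity to B + Lambda.

    Computed as elementwise p-shrinkage at (alpha, u) followed by row-wise
    group shrinkage at (beta, v) — the standard sparse-group prox
    decomposition.  Penalty weights are divided by rho so the proximity term
    keeps unit weight.
    """
    V = state.B + state.Lambda
    V = p_shrink(V, settings.alpha / settings.rho, settings.u)
    return _shrink_rows(V, settings.beta / settings.rho, settings.v)


def _standardize(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    return (M - mu) / sd


def solve_ncadmm(
    X: np.ndarray,
    Y: np.ndarray,
    settings: SolverSettings | None = None,
) -> CoefficientState:
    """Run the nonconvex ADMM to convergence or max_iter.

    Each iteration applies the W-update (shrinkage), the B-update (ridge-like
    linear solve) and the dual step Lambda <- Lambda - (W - B).
    Convergence is declared when the primal residual max|W - B| falls below
    ``tol``.  A residual that grows for 50 consecutive iterations raises
    :class:`ConvergenceError`.

    Columns of X and Y are standardized by default so the penalty weights
    are comparable across features; coefficients are reported on the
    standardized scale.
    """
    if settings is None:
        settings = SolverSettings()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValidationError("X and Y must have the same number of rows")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValidationError("X and Y must be finite")
    if settings.standardize:
        X = _standardize(X)
        Y = _standardize(Y)

    P, Q = X.shape[1], Y.shape[1]
    rho = settings.rho
    A = X.T @ X + rho * np.eye(P)
    cho = cho_factor(A)
    XtY = X.T @ Y

    state = CoefficientState(
        B=np.zeros((P, Q)), W=np.zeros((P, Q)), Lambda=np.zeros((P, Q))
    )
    prev_res = np.inf
    n_growing = 0
    for it in range(1, settings.max_iter + 1):
        state.W = update_W(state, settings)
        rhs = XtY + rho * (state.W - state.Lambda)
        state.B = cho_solve(cho, rhs)
        # scaled-dual ascent: with the proximity term (rho/2)||W - B - Lambda||^2
        # the multiplier steps by the raw constraint violation
        state.Lambda = state.Lambda - (state.W - state.B)
        res = float(np.max(np.abs(state.W - state.B))) if P and Q else 0.0
        state.n_iter = it
        state.primal_residual = res
        if res <= settings.tol:
            state.converged = True
            break
        n_growing = n_growing + 1 if res > prev_res else 0
        if n_growing >= 50:
            raise ConvergenceError(
                f"primal residual grew for 50 consecutive iterations "
                f"(after {it} iterations, residual {res:.3e})"
            )
        prev_res = res
    return state


def augmented_objective(
    state: CoefficientState,
    X: np.ndarray,
    Y: np.ndarray,
    settings: SolverSettings,
) -> float:
    """Augmented objective in the convex case (u = v = 1); used by tests."""
    fit = 0.5 * np.linalg.norm(X @ state.B - Y) ** 2
    pen = settings.alpha * np.abs(state.W).sum() + settings.beta * np.linalg.norm(
        state.W, axis=1
    ).sum()
    prox = 0.5 * settings.rho * np.linalg.norm(state.W - state.B - state.Lambda) ** 2
    return float(fit + pen + prox)
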