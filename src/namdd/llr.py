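"""L1-regularized logistic regression linking gene expression to disease.

Fits  min_theta  sum_i -log p(z_i | y_i; theta) + lambda ||theta||_1  by
proximal gradient descent with backtracking line search.  The nonzero
support of theta defines the gene-disease edges of the association network.
An unpenalized intercept is included by default (class imbalance in
half-samples otherwise biases selection); it can be disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import ValidationError

logger = logging.getLogger("namdd")

__all__ = ["LogisticModel", "predict_prob", "fit_llr"]

SUPPORT_TOL = 1e-8  # |theta_q| above this counts as a selected gene


@dataclass
class LogisticModel:
    theta: np.ndarray
    intercept: float
    lam: float
    converged: bool = True
    objective: float = np.nan

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.theta) > SUPPORT_TOL)


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def predict_prob(model: LogisticModel, y: np.ndarray) -> float:
    """P(z = 1 | y) = sigmoid(theta' y + intercept)."""
    y = np.asarray(y, dtype=float)
    if y.shape != model.theta.shape:
        raise ValidationError(
            f"feature vector length {y.shape} does not match "
            f"coefficient length {model.theta.shape}"
        )
    return float(_sigmoid(np.atleast_1d(model.theta @ y + model.intercept))[0])


def _neg_loglik(Y: np.ndarray, z: np.ndarray, theta: np.ndarray, b: float) -> float:
    t = Y @ theta + b
    # -log p = log(1 + exp(-t)) for z=1, log(1 + exp(t)) for z=0
    return float(np.sum(np.logaddexp(0.0, t) - z * t))


def _grad(Y: np.ndarray, z: np.ndarray, theta: np.ndarray, b: float):
    r = _sigmoid(Y @ theta + b) - z
    return Y.T @ r, float(r.sum())


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(0.0, np.abs(x) - t)


def fit_llr(
    Y: np.ndarray,
    z: np.ndarray,
    lam: float,
    max_iter: int = 2000,
    tol: float = 1e-8,
    fit_intercept: bool = True,
) -> LogisticModel:
    """Fit the L1-penalized logistic model by ISTA with backtracking.

    Stops when the objective decrease falls below ``tol``; on hitting
    ``max_iter`` a convergence warning is logged and the final iterate
    returned.
    """
    Y = np.asarray(Y, dtype=float)
    z = np.asarray(z, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    classes = set(np.unique(z))
    if not classes <= {0.0, 1.0} or len(classes) < 2:
        raise ValidationError("z must contain both classes 0 and 1")

    n, q = Y.shape
    theta = np.zeros(q)
    b = 0.0
    design = np.hstack([Y, np.ones((n, 1))]) if fit_intercept else Y
    step = 4.0 / max(np.linalg.norm(design, ord=2) ** 2, 1e-12)  # 1/L, L <= ||[Y,1]||^2/4
    obj = _neg_loglik(Y, z, theta, b) + lam * np.abs(theta).sum()
    converged = False
    for _ in range(max_iter):
        g_theta, g_b = _grad(Y, z, theta, b)
        s = step
        for _ls in range(60):
            theta_new = _soft(theta - s * g_theta, s * lam)
            b_new = b - s * g_b if fit_intercept else 0.0
            obj_new = _neg_loglik(Y, z, theta_new, b_new) + lam * np.abs(theta_new).sum()
            if obj_new <= obj + 1e-12:
                break
            s *= 0.5
        if obj - obj_new < tol * max(1.0, abs(obj)):
            theta, b, obj = theta_new, b_new, obj_new
            converged = True
            break
        theta, b, obj = theta_new, b_new, obj_new
    if not converged:
        logger.warning("fit_llr reached max_iter=%d, final objective %.6g", max_iter, obj)
    return LogisticModel(theta=theta, intercept=b, lam=lam, converged=converged, objective=obj)


def logistic_deviance(model: LogisticModel, Y: np.ndarray, z: np.ndarray) -> float:
    """Mean held-out deviance 2/n * sum -log p(z|y); used by cross-validation."""
    Y = np.asarray(Y, dtype=float)
    z = np.asarray(z, dtype=float)
    return 2.0 * _neg_loglik(Y, z, model.theta, model.intercept) / len(z)
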