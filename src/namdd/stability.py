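"""Stability selection over the two regression layers.

The sample set is halved T times; the sparse-group solver is refit on each
half for the methylation-gene layer and the L1-logistic model for the
gene-disease layer.  An edge's score is the fraction of refits in which its
coefficient is nonzero; edges with score >= phi are selected.  Under the
usual exchangeability conditions the expected number of false selections per
gene is bounded by c^2 / ((2 phi - 1) P), where c is the number of nonzero
coefficients the solver reports at the cross-validated penalties.

Penalty weights are cross-validated once on the full data and held fixed
across the T half-sample refits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .core_io import AnalysisConfig, ConvergenceError, ValidationError
from .llr import SUPPORT_TOL, fit_llr, logistic_deviance
from .ncadmm import SolverSettings, solve_ncadmm

logger = logging.getLogger("namdd")

__all__ = [
    "EdgeScoreSet",
    "StabilityRun",
    "make_subsamples",
    "stability_select_mg",
    "stability_select_gd",
    "expected_fp_bound",
    "cross_validate",
]


@dataclass
class EdgeScoreSet:
    """Selection frequencies for both edge layers.

    mg_scores is P x Q (methylation -> gene), gd_scores is length Q
    (gene -> disease); every entry is a multiple of 1/T in [0, 1].
    """

    mg_scores: np.ndarray
    gd_scores: np.ndarray
    T: int
    phi: float
    site_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def selected_mg(self) -> np.ndarray:
        """Boolean P x Q mask of selected methylation-gene edges."""
        return self.mg_scores >= self.phi

    def selected_gd(self) -> np.ndarray:
        """Boolean length-Q mask of selected gene-disease edges."""
        return self.gd_scores >= self.phi


@dataclass
class StabilityRun:
    subsample_indices: list[np.ndarray]
    selection_counts: np.ndarray
    n_effective: int  # T minus failed refits
    seed: int


def make_subsamples(
    N: int, T: int, z: np.ndarray, seed: int
) -> list[np.ndarray]:
    """T class-stratified half-samples of floor(N/2) distinct indices.

    Stratification keeps both classes present in every half-sample so the
    logistic layer is always fittable; each class contributes about half of
    its members.
    """
    if N < 4:
        raise ValidationError("need N >= 4 for half-sampling")
    if T < 1:
        raise ValidationError("T must be >= 1")
    z = np.asarray(z)
    half = N // 2
    idx0 = np.flatnonzero(z == 0)
    idx1 = np.flatnonzero(z == 1)
    n0 = len(idx0) // 2
    n1 = len(idx1) // 2
    extra = half - n0 - n1  # 0, 1 or 2 from odd class sizes
    if len(idx0) and len(idx1) and (n0 == 0 or n1 == 0):
        raise ValidationError("a class is too small for stratified half-sampling")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(T):
        take0 = rng.permutation(idx0)[:n0]
        take1 = rng.permutation(idx1)[:n1]
        sub = np.concatenate([take0, take1])
        if extra:
            rest = np.setdiff1d(np.arange(N), sub, assume_unique=False)
            sub = np.concatenate([sub, rng.permutation(rest)[:extra]])
        out.append(np.sort(sub))
    return out


def _spawn_seeds(seed: int, T: int) -> np.ndarray:
    """Deterministic per-subsample seeds from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=T)


def stability_select_mg(
    X: np.ndarray,
    Y: np.ndarray,
    config: AnalysisConfig,
    solver: SolverSettings,
    z: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, StabilityRun]:
    """Selection frequencies of methylation-gene edges over T half-samples.

    Returns (mg_scores P x Q, run record).  A half-sample whose solve
    diverges is dropped from the scoring denominator with a warning; more
    than 10% failures is a hard error.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    N = X.shape[0]
    if z is None:
        z = np.zeros(N, dtype=int)  # unstratified fallback for label-free use
        subs = [
            np.sort(np.random.default_rng(s).permutation(N)[: N // 2])
            for s in _spawn_seeds(config.seed if seed is None else seed, config.T)
        ]
    else:
        subs = make_subsamples(N, config.T, z, config.seed if seed is None else seed)
    counts = np.zeros((X.shape[1], Y.shape[1]), dtype=int)
    n_failed = 0
    for sub in subs:
        try:
            state = solve_ncadmm(X[sub], Y[sub], solver)
        except ConvergenceError:
            n_failed += 1
            logger.warning("half-sample solve diverged; dropping it from scoring")
            continue
        counts += np.abs(state.W) > SUPPORT_TOL
    n_eff = config.T - n_failed
    if n_failed > 0.1 * config.T:
        raise ConvergenceError(
            f"{n_failed}/{config.T} half-sample solves diverged"
        )
    scores = counts / max(n_eff, 1)
    run = StabilityRun(
        subsample_indices=subs,
        selection_counts=counts,
        n_effective=n_eff,
        seed=config.seed if seed is None else seed,
    )
    return scores, run


def _standardize_cols(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    return (M - mu) / sd


def stability_select_gd(
    Y: np.ndarray,
    z: np.ndarray,
    config: AnalysisConfig,
    lambda_star: float,
    seed: int | None = None,
) -> tuple[np.ndarray, StabilityRun]:
    """Selection frequencies of gene-disease edges over T half-samples.

    Gene columns are standardized within each half-sample (matching the
    regression layer's convention) so one lambda applies to all genes.
    """
    Y = np.asarray(Y, dtype=float)
    z = np.asarray(z)
    N = Y.shape[0]
    subs = make_subsamples(N, config.T, z, config.seed if seed is None else seed)
    counts = np.zeros(Y.shape[1], dtype=int)
    for sub in subs:
        Ysub = _standardize_cols(Y[sub]) if config.standardize else Y[sub]
        model = fit_llr(Ysub, z[sub], lambda_star)
        counts[model.support] += 1
    scores = counts / config.T
    run = StabilityRun(
        subsample_indices=subs,
        selection_counts=counts,
        n_effective=config.T,
        seed=config.seed if seed is None else seed,
    )
    return scores, run


def scores_from_counts(counts: np.ndarray, T: int) -> np.ndarray:
    """Edge score = selection count / T."""
    if T < 1:
        raise ValidationError("T must be >= 1")
    counts = np.asarray(counts)
    if (counts < 0).any() or (counts > T).any():
        raise ValidationError("counts must lie in [0, T]")
    return counts / T


def expected_fp_bound(phi: float, c: float, P: int) -> float:
    """Upper bound on expected false selections per gene: c^2 / ((2 phi - 1) P)."""
    if phi <= 0.5:
        raise ValidationError("the false-positive bound requires phi > 0.5")
    if P < 1 or c < 0:
        raise ValidationError("need P >= 1 and c >= 0")
    return (1.0 / (2.0 * phi - 1.0)) * c**2 / P


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    z: np.ndarray,
    config: AnalysisConfig,
    solver_template: SolverSettings | None = None,
) -> tuple[float, float, float]:
    """Choose (alpha*, beta*) by held-out squared error of the sparse-group
    fit and lambda* by held-out logistic deviance, over the config grids.

    Folds are seeded; the logistic folds are stratified on z.  Returns the
    grid points with minimal mean held-out loss (ties to the first, i.e.
    most-penalized-last ordering as listed in the grids).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    z = np.asarray(z)
    N = X.shape[0]
    n_folds = min(config.n_cv_folds, N)
    if n_folds > N:
        raise ValidationError("n_cv_folds exceeds the number of samples")
    if solver_template is None:
        solver_template = SolverSettings(u=config.u, v=config.v,
                                         max_iter=config.max_iter, tol=config.tol,
                                         rho=config.rho,
                                         standardize=config.standardize)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    folds = list(kf.split(X))
    best_ab, best_err = None, np.inf
    for alpha in config.alpha_grid:
        for beta in config.beta_grid:
            settings = SolverSettings(
                alpha=alpha, beta=beta, u=solver_template.u, v=solver_template.v,
                max_iter=solver_template.max_iter, tol=solver_template.tol,
                rho=solver_template.rho, standardize=solver_template.standardize,
            )
            errs = []
            for tr, te in folds:
                state = solve_ncadmm(X[tr], Y[tr], settings)
                Xte, Yte = X[te], Y[te]
                if settings.standardize:
                    mu, sd = X[tr].mean(0), X[tr].std(0)
                    sd[sd == 0] = 1.0
                    Xte = (Xte - mu) / sd
                    muy, sdy = Y[tr].mean(0), Y[tr].std(0)
                    sdy[sdy == 0] = 1.0
                    Yte = (Yte - muy) / sdy
                errs.append(0.5 * np.linalg.norm(Xte @ state.W - Yte) ** 2 / len(te))
            err = float(np.mean(errs))
            if err < best_err - 1e-12:
                best_ab, best_err = (alpha, beta), err
    alpha_star, beta_star = best_ab

    lam_star, best_dev = None, np.inf
    for attempt in range(5):
        try:
            skf = StratifiedKFold(
                n_splits=min(n_folds, int(min(np.bincount(z)))),
                shuffle=True,
                random_state=config.seed + attempt,
            )
            lfolds = list(skf.split(Y, z))
            for lam in config.lambda_grid:
                devs = []
                for tr, te in lfolds:
                    if len(np.unique(z[tr])) < 2:
                        raise ValidationError("single-class training fold")
                    if config.standardize:
                        mu, sd = Y[tr].mean(0), Y[tr].std(0)
                        sd[sd == 0] = 1.0
                        Ytr, Yte = (Y[tr] - mu) / sd, (Y[te] - mu) / sd
                    else:
                        Ytr, Yte = Y[tr], Y[te]
                    model = fit_llr(Ytr, z[tr], lam)
                    devs.append(logistic_deviance(model, Yte, z[te]))
                dev = float(np.mean(devs))
                if dev < best_dev - 1e-12:
                    lam_star, best_dev = lam, dev
            break
        except ValidationError:
            if attempt == 4:
                raise ValidationError(
                    "could not build two-class folds after 5 reseeds"
                )
    return float(alpha_star), float(beta_star), float(lam_star)
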