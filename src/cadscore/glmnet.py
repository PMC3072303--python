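"""Penalized logistic regression with per-column penalty factors.

L1 (lasso) paths are computed glmnet-style: an outer IRLS quadratic
approximation with inner cyclic coordinate descent and warm starts along a
log-spaced lambda grid.  L2 (ridge) fits use penalized Newton iteration.
Columns with penalty factor 0 (here: the sex and age covariates) are never
shrunk.  The objective in both cases is

    f(beta) = -(1/n) sum loglik_i + lambda * sum_j pf_j * P(beta_j)

with P = |.| for the lasso and P = (.)^2 / 2 for ridge; an unpenalized
intercept is always included and is supplied by these routines, not the
caller.

Cross-validation selects lambda at minimum mean held-out binomial deviance
over stratified folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .containers import ConfigurationError, DataError

_ETA_CAP = 30.0
_W_FLOOR = 1e-5


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Total binomial deviance (-2 loglik)."""
    eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
    return float(2.0 * np.sum(np.log1p(np.exp(eta)) - y * eta))


def _safe_logit(p: float) -> float:
    p = min(max(p, 1e-8), 1 - 1e-8)
    return float(np.log(p / (1 - p)))


def ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                   penalty_factor: np.ndarray | None = None,
                   max_iter: int = 200, tol: float = 1e-12,
                   theta0: np.ndarray | None = None):
    """Penalized Newton fit of the ridge logistic objective.

    Returns (intercept, beta, hessian) where ``hessian`` is the penalized
    Hessian of the *total* (not mean) objective at the optimum, usable for
    approximate standard errors.  ``theta0`` warm-starts the iteration.
    """
    n, p = X.shape
    if lam < 0:
        raise ConfigurationError("lambda must be >= 0")
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    theta = np.zeros(p + 1) if theta0 is None else np.asarray(theta0, float).copy()
    Z = np.column_stack([np.ones(n), X])
    pen = np.concatenate([[0.0], pf]) * lam  # per-parameter ridge weight
    H = None
    for _ in range(max_iter):
        eta = np.clip(Z @ theta, -_ETA_CAP, _ETA_CAP)
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), _W_FLOOR)
        grad = Z.T @ (y - mu) / n - pen * theta
        H = Z.T @ (Z * w[:, None]) / n + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise DataError("singular penalized Hessian; increase lambda") from None
        theta = theta + step
        if np.max(np.abs(step)) < tol:
            break
    hess_total = H * n
    return float(theta[0]), theta[1:], hess_total


try:  # numba accelerates the coordinate loops ~30x; plain numpy otherwise
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _cd_kernel_py(Z, zresp, w, beta, lam, pen_par, max_iter, tol):
    # covariance-update coordinate descent: work against the weighted Gram
    # matrix so each coordinate update is O(p), not O(n)
    n, p = Z.shape
    Zw = Z * (w / n)[:, None]
    G = Zw.T @ Z          # G[j, k] = sum_i w_i Z_ij Z_ik / n
    b = Zw.T @ zresp      # b[j] = sum_i w_i Z_ij z_i / n
    q = G @ beta
    for it in range(max_iter):
        full_sweep = True
        for _ in range(max_iter):
            max_delta = 0.0
            for j in range(p):
                if (not full_sweep) and beta[j] == 0.0 and pen_par[j] > 0:
                    continue
                dj = G[j, j]
                if dj <= 0:
                    continue
                bj_old = beta[j]
                rho = b[j] - q[j] + dj * bj_old
                thr = lam * pen_par[j]
                if thr > 0:
                    mag = abs(rho) - thr
                    bj_new = (np.sign(rho) * mag / dj) if mag > 0 else 0.0
                else:
                    bj_new = rho / dj
                if bj_new != bj_old:
                    beta[j] = bj_new
                    q += G[:, j] * (bj_new - bj_old)
                    delta = abs(bj_new - bj_old)
                    if delta > max_delta:
                        max_delta = delta
            if full_sweep:
                stable_full = max_delta < tol
                full_sweep = False
                if stable_full:
                    return beta
            elif max_delta < tol:
                break
    return beta


if njit is not None:
    _cd_kernel = njit(cache=True)(_cd_kernel_py)
else:  # pragma: no cover
    _cd_kernel = _cd_kernel_py


def _standardize(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def lasso_logistic_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                        penalty_factor: np.ndarray | None = None,
                        max_irls: int = 15, tol: float = 1e-7):
    """L1-penalized logistic coefficients along a decreasing lambda grid.

    Returns (intercepts[k], betas[k, p]) with warm starts between grid
    points.  Penalty-factor-0 columns (and the intercept) are refit
    unpenalized at every lambda.  As in glmnet's default, columns are
    standardized internally — the L1 penalty acts on the standardized
    scale — and coefficients are returned on the original scale.
    """
    n, p = X.shape
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    Xs, mean, sd = _standardize(np.asarray(X, float))
    Z = np.ascontiguousarray(np.column_stack([np.ones(n), Xs]))
    pen_par = np.ascontiguousarray(np.concatenate([[0.0], pf]))
    y = np.ascontiguousarray(y, dtype=float)
    theta = np.zeros(p + 1)
    intercepts = np.empty(len(lambdas))
    betas = np.empty((len(lambdas), p))
    null_dev = _deviance(y, np.full(n, _safe_logit(y.mean())))
    stopped = False
    for k, lam in enumerate(lambdas):
        if not stopped:
            for _ in range(max_irls):
                eta = np.clip(Z @ theta, -_ETA_CAP, _ETA_CAP)
                mu = expit(eta)
                w = np.maximum(mu * (1 - mu), _W_FLOOR)
                zresp = eta + (y - mu) / w
                theta_old = theta.copy()
                theta = _cd_kernel(Z, np.ascontiguousarray(zresp),
                                   np.ascontiguousarray(w), theta, float(lam),
                                   pen_par, 30, 1e-9)
                if np.max(np.abs(theta - theta_old)) < tol:
                    break
                if np.max(np.abs(theta)) > 1e3:  # separated: stop refining
                    stopped = True
                    break
            # glmnet-style early exit: once 99% of the null deviance is
            # explained the remaining path is a separation artefact
            if _deviance(y, Z @ theta) < 1e-2 * null_dev:
                stopped = True
        beta_orig = theta[1:] / sd
        intercepts[k] = theta[0] - np.dot(beta_orig, mean)
        betas[k] = beta_orig
    return intercepts, betas


def lambda_grid(X: np.ndarray, y: np.ndarray,
                penalty_factor: np.ndarray | None = None,
                n_lambda: int = 100, lambda_min_ratio: float = 1e-4):
    """Data-driven lambda grid: from the smallest lambda zeroing every

    penalized coefficient (computed at the unpenalized-columns-only null
    fit) down to ``lambda_max * lambda_min_ratio``, log-spaced."""
    n, p = X.shape
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    Xs, _, _ = _standardize(np.asarray(X, float))  # penalty acts on std scale
    free = pf == 0
    if free.any():
        _, beta_free, _ = ridge_logistic(Xs[:, free], y, lam=0.0,
                                         penalty_factor=np.zeros(free.sum()))
        b0 = _null_intercept(Xs[:, free], y, beta_free)
        eta0 = b0 + Xs[:, free] @ beta_free
    else:
        pbar = y.mean()
        eta0 = np.full(n, np.log(pbar / (1 - pbar)))
    mu0 = expit(np.clip(eta0, -_ETA_CAP, _ETA_CAP))
    score = np.abs(Xs.T @ (y - mu0)) / n
    with np.errstate(divide="ignore"):
        lam_max = np.max(np.where(pf > 0, score / np.where(pf > 0, pf, 1.0), 0.0))
    lam_max = max(lam_max * 1.000001, 1e-6)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def _null_intercept(Xfree, y, beta_free):
    # the free-column ridge fit already contains its own intercept; refit
    # cheaply to recover it
    from scipy.optimize import brentq
    off = Xfree @ beta_free

    def g(b0):
        return np.mean(expit(np.clip(b0 + off, -_ETA_CAP, _ETA_CAP))) - y.mean()

    try:
        return brentq(g, -30, 30)
    except ValueError:
        return 0.0


@dataclass
class CVCurve:
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    lambda_best: float
    se_deviance: np.ndarray | None = None
    lambda_min: float | None = None


def _folds(y, n_folds, seed):
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cv_lasso(X, y, penalty_factor=None, n_folds: int = 10, seed: int = 0,
             n_lambda: int = 100, lambda_min_ratio: float = 1e-4,
             rule: str = "1se"):
    """10-fold (by default) cross-validation of the lasso path.

    ``rule="min"`` takes lambda at the minimum mean held-out deviance;
    ``rule="1se"`` (default) takes the largest lambda whose mean deviance is
    within one standard error of that minimum — the conventional parsimony
    rule, which markedly reduces spurious selections.  Returns
    (intercept, beta, CVCurve) for the whole-data fit at the chosen lambda.
    """
    if rule not in ("min", "1se"):
        raise ConfigurationError(f"unknown CV rule {rule!r}")
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise DataError("outcome is degenerate (single class)")
    lambdas = lambda_grid(X, y, penalty_factor, n_lambda, lambda_min_ratio)
    dev = np.zeros((n_folds, len(lambdas)))
    for f, (tr, te) in enumerate(_folds(y, n_folds, seed)):
        ints, betas = lasso_logistic_path(X[tr], y[tr], lambdas, penalty_factor)
        eta_te = ints[:, None] + betas @ X[te].T
        for k in range(len(lambdas)):
            dev[f, k] = _deviance(y[te], eta_te[k]) / len(te)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    kmin = int(np.argmin(mean_dev))
    if rule == "1se":
        best = int(np.min(np.flatnonzero(
            mean_dev <= mean_dev[kmin] + se_dev[kmin])))
    else:
        best = kmin
    ints, betas = lasso_logistic_path(X, y, lambdas, penalty_factor)
    return ints[best], betas[best], CVCurve(lambdas, mean_dev,
                                            float(lambdas[best]), se_dev,
                                            float(lambdas[kmin]))


def cv_ridge(X, y, penalty_factor=None, n_folds: int = 10, seed: int = 0,
             n_lambda: int = 100, lambda_min_ratio: float = 1e-4):
    """CV over a ridge lambda grid; returns (intercept, beta, hessian, CVCurve)."""
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise DataError("outcome is degenerate (single class)")
    lambdas = lambda_grid(X, y, penalty_factor, n_lambda, lambda_min_ratio)
    dev = np.zeros((n_folds, len(lambdas)))
    for f, (tr, te) in enumerate(_folds(y, n_folds, seed)):
        theta = None  # warm start along the descending lambda grid
        for k, lam in enumerate(lambdas):
            b0, beta, _ = ridge_logistic(X[tr], y[tr], lam, penalty_factor,
                                         max_iter=50, theta0=theta)
            theta = np.concatenate([[b0], beta])
            dev[f, k] = _deviance(y[te], b0 + X[te] @ beta) / len(te)
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    lam = float(lambdas[best])
    b0, beta, hess = ridge_logistic(X, y, lam, penalty_factor)
    return b0, beta, hess, CVCurve(lambdas, mean_dev, lam)
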