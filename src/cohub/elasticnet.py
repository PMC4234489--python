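"""Elastic-net penalized logistic regression by cyclic coordinate descent.

Minimizes, over intercept b0 and coefficients b,

    (1/n) * sum_i log(1 + exp(-(2 y_i - 1) * (b0 + x_i b)))
        + lambda * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2)

with y in {0, 1}, an unpenalized intercept, and predictors standardized
internally (coefficients are reported on the original scale).  The solver
is iteratively reweighted least squares (quadratic approximation of the
log-likelihood) with cyclic coordinate descent on each weighted
least-squares subproblem — the classical glmnet strategy.  At
lambda >= lambda_max = max_j |x_j^T (y - ybar)| / (n * alpha) the solution
is exactly the all-zero coefficient vector with the class-balance
intercept.

The inner loops are numba-compiled; the first call in a process pays a
one-off compilation cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

_PMIN = 1e-5  # probability clip in the IRLS weights


@njit(cache=False)
def _soft_threshold(z: float, g: float) -> float:
    # the (1 + 1e-12) guard keeps coefficients exactly zero at the
    # lambda_max boundary despite summation-order rounding
    thr = g * (1.0 + 1e-12)
    if z > thr:
        return z - g
    if z < -thr:
        return z + g
    return 0.0


@njit(cache=False, fastmath=True)
def _sweep(X, w, r, beta, xv, active, lam_l1, lam_l2, n):
    """One coordinate-descent pass over ``active`` columns; returns max change."""
    dmax = 0.0
    for j in active:
        g = 0.0
        for i in range(n):
            g += w[i] * X[i, j] * r[i]
        g = g / n + xv[j] * beta[j]
        bj = _soft_threshold(g, lam_l1) / (xv[j] + lam_l2)
        d = bj - beta[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            beta[j] = bj
            if abs(d) > dmax:
                dmax = abs(d)
    return dmax


@njit(cache=False, fastmath=True)
def _cd_weighted_ls(X, w, z, beta0, beta, lam_l1, lam_l2, tol, max_iter):
    """Coordinate descent on the penalized weighted least-squares subproblem.

    After each full pass, iterates on the current active set until it
    stabilizes (glmnet strategy), then re-checks all coordinates.
    """
    n, p = X.shape
    r = z - beta0 - X @ beta
    xv = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        xv[j] = s / n
    wsum = w.sum()
    all_cols = np.arange(p)
    it = 0
    while it < max_iter:
        d0 = 0.0
        for i in range(n):
            d0 += w[i] * r[i]
        d0 /= wsum
        beta0 += d0
        for i in range(n):
            r[i] -= d0
        dmax = _sweep(X, w, r, beta, xv, all_cols, lam_l1, lam_l2, n)
        it += 1
        if max(dmax, abs(d0)) < tol:
            break
        active = np.flatnonzero(beta)
        while it < max_iter:
            d = _sweep(X, w, r, beta, xv, active, lam_l1, lam_l2, n)
            it += 1
            if d < tol:
                break
    return beta0


@njit(cache=False)
def _irls_enet(X, y, lam, alpha, tol, max_iter, beta0_init, beta_init):
    n, p = X.shape
    beta = beta_init.copy()
    beta0 = beta0_init
    lam_l1 = lam * alpha
    lam_l2 = lam * (1.0 - alpha)
    converged = False
    n_iter = 0
    for outer in range(max_iter):
        n_iter = outer + 1
        eta = beta0 + X @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        for i in range(n):
            if prob[i] < _PMIN:
                prob[i] = _PMIN
            elif prob[i] > 1.0 - _PMIN:
                prob[i] = 1.0 - _PMIN
        w = prob * (1.0 - prob)
        z = eta + (y - prob) / w
        old0 = beta0
        old = beta.copy()
        beta0 = _cd_weighted_ls(X, w, z, beta0, beta, lam_l1, lam_l2, tol * 0.1, 200)
        dmax = abs(beta0 - old0)
        for j in range(p):
            if abs(beta[j] - old[j]) > dmax:
                dmax = abs(beta[j] - old[j])
        if dmax < tol:
            converged = True
            break
    return beta0, beta, n_iter, converged


@dataclass
class ElasticNetFit:
    """Fitted elastic-net logistic model (original predictor scale)."""

    intercept: float
    coefficients: np.ndarray
    lam: float
    alpha: float
    converged: bool
    n_iter: int
    # standardized-scale solution and column statistics, kept for
    # optimality (KKT) diagnostics
    intercept_std: float = 0.0
    coefficients_std: np.ndarray | None = None
    col_mean: np.ndarray | None = None
    col_sd: np.ndarray | None = None

    @property
    def nonzero(self) -> np.ndarray:
        return np.flatnonzero(self.coefficients != 0.0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.asarray(X, dtype=float) @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> str:
        lines = [
            "Elastic-net logistic regression",
            "-" * 38,
            f"lambda: {self.lam:.6g}   alpha: {self.alpha}   "
            f"converged: {self.converged} ({self.n_iter} IRLS iterations)",
            f"intercept: {self.intercept:+.4f}",
            f"nonzero coefficients: {self.nonzero.size} / {self.coefficients.size}",
        ]
        for j in self.nonzero:
            lines.append(f"  x{j}: {self.coefficients[j]:+.4f}")
        return "\n".join(lines)


class ElasticNetLogistic:
    """Elastic-net penalized logistic regression model.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_features)
    y : ndarray of 0/1 labels
    alpha : float in [0, 1]
        Penalty mixing (1 = lasso, 0 = ridge).
    tol, max_iter
        IRLS convergence tolerance and iteration cap.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        alpha: float = 0.5,
        tol: float = 1e-7,
        max_iter: int = 100,
    ) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be n_samples x n_features and y one label per sample")
        if not np.isin(y, [0.0, 1.0]).all():
            raise ValueError("y must be binary 0/1")
        if (y == 1).sum() < 2 or (y == 0).sum() < 2:
            raise ValueError("need at least 2 samples per class")
        if not (0.0 <= alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        self.X = X
        self.y = y
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

        self._mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._constant = sd == 0
        sd = np.where(self._constant, 1.0, sd)
        self._sd = sd
        self._Z = (X - self._mean) / sd
        self._Z[:, self._constant] = 0.0  # constant predictors can never enter

    @property
    def lambda_max(self) -> float:
        """Smallest lambda at which the coefficient vector is all-zero."""
        n = self.y.size
        ybar = self.y.mean()
        grad = np.abs(self._Z.T @ (self.y - ybar)) / n
        return float(grad.max() / max(self.alpha, 1e-3))

    def lambda_path(self, n_lambdas: int = 20, eps: float = 1e-2) -> np.ndarray:
        """Log-spaced lambda path from lambda_max down to eps * lambda_max."""
        lmax = self.lambda_max
        return np.geomspace(lmax, lmax * eps, n_lambdas)

    def fit(self, lam: float, warm: ElasticNetFit | None = None) -> ElasticNetFit:
        """Solve at one penalty strength (optionally warm-started)."""
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        ybar = self.y.mean()
        beta0 = float(np.log(ybar / (1.0 - ybar)))
        beta = np.zeros(self.X.shape[1])
        if warm is not None and warm.coefficients_std is not None:
            beta0 = warm.intercept_std
            beta = warm.coefficients_std.copy()
        beta0, beta, n_iter, converged = _irls_enet(
            self._Z, self.y, lam, self.alpha, self.tol, self.max_iter, beta0, beta
        )
        if not converged:
            logger.warning(
                "elastic net did not converge in %d IRLS iterations (lambda=%.4g)",
                self.max_iter, lam,
            )
        coef = beta / self._sd
        coef[self._constant] = 0.0
        intercept = beta0 - float(self._mean @ coef)
        return ElasticNetFit(
            intercept=intercept,
            coefficients=coef,
            lam=float(lam),
            alpha=self.alpha,
            converged=bool(converged),
            n_iter=int(n_iter),
            intercept_std=float(beta0),
            coefficients_std=beta,
            col_mean=self._mean,
            col_sd=self._sd,
        )

    def fit_path(self, lambdas: np.ndarray | None = None) -> list[ElasticNetFit]:
        """Warm-started fits over a decreasing lambda path."""
        if lambdas is None:
            lambdas = self.lambda_path()
        lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
        fits: list[ElasticNetFit] = []
        warm = None
        for lam in lambdas:
            warm = self.fit(lam, warm=warm)
            fits.append(warm)
        return fits

    def fit_cv(
        self,
        n_folds: int = 5,
        n_lambdas: int = 20,
        seed: int = 0,
    ) -> ElasticNetFit:
        """Choose lambda by k-fold cross-validated deviance, then refit.

        Folds are stratified by class; the minimum-mean-deviance lambda
        wins (ties toward the stronger penalty).
        """
        from sklearn.model_selection import StratifiedKFold

        lambdas = self.lambda_path(n_lambdas)
        deviance = np.zeros(lambdas.size)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for train, test in skf.split(self.X, self.y):
            sub = ElasticNetLogistic(
                self.X[train], self.y[train], alpha=self.alpha,
                tol=self.tol, max_iter=self.max_iter,
            )
            for i, fit in enumerate(sub.fit_path(lambdas)):
                p = np.clip(fit.predict_proba(self.X[test]), _PMIN, 1 - _PMIN)
                yt = self.y[test]
                deviance[i] += -2.0 * float(yt @ np.log(p) + (1 - yt) @ np.log(1 - p))
        best = int(np.argmin(deviance))  # lambdas sorted decreasing by fit_path order
        lambdas = np.sort(lambdas)[::-1]
        return self.fit(lambdas[best])

    def max_kkt_violation(self, fit: ElasticNetFit) -> float:
        """Largest violation of the elastic-net optimality conditions.

        On the internal standardized scale, with g the gradient of the
        unpenalized average log-loss plus the ridge term: active
        coefficients require g_j = -lambda*alpha*sign(b_j); zero
        coefficients require |g_j| <= lambda*alpha.
        """
        assert fit.coefficients_std is not None
        n = self.y.size
        eta = fit.intercept_std + self._Z @ fit.coefficients_std
        prob = 1.0 / (1.0 + np.exp(-eta))
        grad = self._Z.T @ (prob - self.y) / n + fit.lam * (1 - fit.alpha) * fit.coefficients_std
        la = fit.lam * fit.alpha
        viol = np.where(
            fit.coefficients_std != 0.0,
            np.abs(grad + la * np.sign(fit.coefficients_std)),
            np.maximum(np.abs(grad) - la, 0.0),
        )
        viol[self._constant] = 0.0
        return float(np.max(np.append(viol, abs((prob - self.y).mean()))))
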