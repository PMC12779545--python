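"""Regularized linear models used across the pipeline.

Ridge regression is solved in closed form via SVD, which makes sweeping a
regularization grid and predicting many neurons (targets) from the same
design matrix nearly free — the pipeline fits one ridge per timepoint, per
cross-validation fold and per temporal offset, so this path matters.
Logistic regression (for choice decoding) is fit by iteratively reweighted
least squares with an L2 penalty on the weights (not the intercept).
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

#: default regularization grid (log-spaced, 1e-3 ... 1e4)
LAMBDA_GRID = np.logspace(-3, 4, 8)


# ---------------------------------------------------------------------------
# ridge
# ---------------------------------------------------------------------------

class RidgePath:
    """SVD factorization of a (centered) design matrix, reusable across
    regularization strengths and multi-target right-hand sides."""

    def __init__(self, X: np.ndarray, Y: np.ndarray, fit_intercept: bool = True):
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        self.single = Y.ndim == 1
        if self.single:
            Y = Y[:, None]
        self.fit_intercept = fit_intercept
        if fit_intercept:
            self.x_mean = X.mean(axis=0)
            self.y_mean = Y.mean(axis=0)
            X = X - self.x_mean
            Y = Y - self.y_mean
        else:
            self.x_mean = np.zeros(X.shape[1])
            self.y_mean = np.zeros(Y.shape[1])
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        self.s = s
        self.V = Vt.T
        self.UtY = U.T @ Y

    def coef(self, lam: float) -> tuple[np.ndarray, np.ndarray]:
        """Ridge solution for one lambda: (coef (p, m), intercept (m,))."""
        shrink = self.s / (self.s**2 + lam)
        W = self.V @ (shrink[:, None] * self.UtY)
        b = self.y_mean - self.x_mean @ W
        if self.single:
            return W[:, 0], b[0]
        return W, b

    def coef_per_target(self, lams: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ridge solution with a separate lambda per target column."""
        lams = np.atleast_1d(np.asarray(lams, dtype=float))
        shrink = self.s[:, None] / (self.s[:, None] ** 2 + lams[None, :])
        W = self.V @ (shrink * self.UtY)
        b = self.y_mean - self.x_mean @ W
        return W, b


def ridge_solve(X: np.ndarray, Y: np.ndarray, lam: float,
                fit_intercept: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """L2-regularized least squares: argmin ||Y - Xw - b||^2 + lam ||w||^2."""
    return RidgePath(X, Y, fit_intercept=fit_intercept).coef(lam)


def _inner_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [np.sort(part) for part in np.array_split(rng.permutation(n), k)]


def ridge_cv_lambda(X: np.ndarray, Y: np.ndarray, lams: np.ndarray = LAMBDA_GRID,
                    k: int = 5, seed: int = 0) -> np.ndarray:
    """Per-target lambda minimizing k-fold cross-validated squared error."""
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    n, m = Y2.shape
    sse = np.zeros((len(lams), m))
    for test in _inner_folds(n, k, seed):
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        path = RidgePath(X[mask], Y2[mask])
        for j, lam in enumerate(lams):
            W, b = path.coef(lam)
            W = np.atleast_2d(W.T).T
            pred = X[test] @ W + b
            sse[j] += ((Y2[test] - pred) ** 2).sum(axis=0)
    best = np.asarray(lams)[np.argmin(sse, axis=0)]
    return best if Y.ndim > 1 else best[0]


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def fit_logistic(X: np.ndarray, y: np.ndarray, lam: float = 1.0,
                 max_iter: int = 50, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """L2-penalized logistic regression by Newton/IRLS.

    Minimizes the negative log-likelihood + (lam/2)||w||^2; the intercept is
    unpenalized. Returns (weights, intercept). y must be 0/1.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    beta = np.zeros(p + 1)
    Xa = np.hstack([X, np.ones((n, 1))])
    pen = np.full(p + 1, lam)
    pen[-1] = 0.0
    for _ in range(max_iter):
        eta = np.clip(Xa @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Xa.T @ (mu - y) + pen * beta
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = (Xa * w[:, None]).T @ Xa + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta -= step
        if np.max(np.abs(step)) < tol:
            break
    return beta[:-1], beta[-1]


def logistic_cv_lambda(X: np.ndarray, y: np.ndarray, lams: np.ndarray = LAMBDA_GRID,
                       inner: int | str = 5, seed: int = 0) -> float:
    """Lambda minimizing held-out log-loss (k-fold or leave-one-out)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = ([np.array([i]) for i in range(n)] if inner == "loo"
             else _inner_folds(n, int(inner), seed))
    loss = np.zeros(len(lams))
    for test in folds:
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        if len(np.unique(y[mask])) < 2:
            continue
        for j, lam in enumerate(lams):
            w, b = fit_logistic(X[mask], y[mask], lam)
            eta = np.clip(X[test] @ w + b, -30, 30)
            loss[j] += np.sum(np.log1p(np.exp(eta)) - y[test] * eta)
    return float(np.asarray(lams)[np.argmin(loss)])


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC with the midrank tie convention (constant scores -> 0.5)."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y_true, scores))
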