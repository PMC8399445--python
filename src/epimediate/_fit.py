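"""Compact least-squares and Newton logistic solvers.

Used by the mediation machinery, where percentile bootstraps refit both
models hundreds of times per pair; the hot path is plain numpy on
pre-built design matrices.  Estimates and standard errors are checked
against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class RankDeficientError(ValueError):
    """Design matrix is not full rank; names the offending columns."""


class ConvergenceError(RuntimeError):
    pass


def check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise RankDeficientError naming dependent columns if X is rank deficient."""
    n, k = X.shape
    if n < k or np.linalg.matrix_rank(X) < k:
        names = names or [f"x{j}" for j in range(k)]
        bad = []
        # greedy scan: column j is flagged if it adds no rank over columns < j
        rank = 0
        for j in range(k):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == rank:
                bad.append(names[j])
            rank = r
        raise RankDeficientError(f"design is rank deficient; dependent columns: {bad}")


@dataclass
class OlsResult:
    coef: np.ndarray
    cov: np.ndarray        # coefficient covariance, sigma2 * (X'X)^-1
    sigma2: float          # residual variance, RSS / (n - k)
    n: int


def ols(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> OlsResult:
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} observations for {k} coefficients, got {n}")
    check_full_rank(X, names)
    xtx = X.T @ X
    coef = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - k)
    cov = sigma2 * np.linalg.inv(xtx)
    return OlsResult(coef=coef, cov=cov, sigma2=sigma2, n=n)


@dataclass
class LogitResult:
    coef: np.ndarray
    cov: np.ndarray        # inverse observed information at the MLE
    converged: bool
    separated: bool
    n: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def logit(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
    check_rank: bool = True,
) -> LogitResult:
    """Maximum-likelihood logistic regression by Newton-Raphson.

    Separation is flagged when fitted linear predictors diverge
    (|X beta| > 30 while classifying perfectly) or the Hessian becomes
    numerically singular on the way to an unbounded MLE.
    """
    n, k = X.shape
    if check_rank:
        check_full_rank(X, names)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    beta = np.zeros(k)
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    if np.max(np.abs(eta)) > 30:
        # monotone-diverging linear predictor: (quasi-)separation
        pred = eta > 0
        if np.mean(pred == (y > 0.5)) > 0.999:
            separated = True
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = p * (1.0 - p)
    hess = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        separated = True
    return LogitResult(coef=beta, cov=cov, converged=converged and not separated,
                       separated=separated, n=n)
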