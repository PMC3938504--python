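"""Lean Newton-Raphson logistic likelihood maximiser.

Used inside resampling loops (bootstrap forward selection, stepwise walks)
where tens of thousands of small logistic fits are needed and the full
inference machinery of the public estimator would dominate the runtime.
The public model fitting (`ntcpx.model.fit_mle`) remains the reference
implementation; this solver is checked against it in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["newton_logit"]

_MAX_ABS_COEF = 35.0  # |linear predictor| beyond this is numerically saturated


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log p(y | eta) summed, written to stay finite for large |eta|
    return float(-np.sum(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)))


def newton_logit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
):
    """Maximise the binomial log-likelihood of ``y`` on design ``X``.

    ``X`` must already contain an intercept column.  Returns
    ``(beta, loglik, converged)``; ``converged`` is False when the iteration
    ran away (separated data) or stalled, in which case ``beta`` is the last
    stable iterate and ``loglik`` its likelihood.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    ybar = y.mean()
    if 0.0 < ybar < 1.0:
        # initialise the (first) constant column at the null logit
        const_cols = np.where(np.ptp(X, axis=0) == 0)[0]
        if const_cols.size:
            beta[const_cols[0]] = np.log(ybar / (1 - ybar)) / X[0, const_cols[0]]
    ll = _loglik(X @ beta, y)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            return beta, ll, False
        # step-halving line search on the log-likelihood
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = _loglik(X @ cand, y)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        else:
            return beta, ll, False
        improved = ll_new - ll
        beta, ll = cand, ll_new
        if np.abs(beta).max() > _MAX_ABS_COEF:
            return beta, ll, False
        if improved < tol and np.abs(grad).max() < 1e-5 * max(1.0, n):
            return beta, ll, True
        if improved < tol:
            return beta, ll, True
    return beta, ll, False
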