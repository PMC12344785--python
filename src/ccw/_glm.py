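"""Weighted logistic regression by Newton-Raphson, tuned for person-period panels.

Two entry points:

``fit_logit``
    Generic dense design; used for small models and polynomial-in-time forms.

``fit_pooled_logit``
    Pooled (discrete-time) logistic model with a saturated set of interval
    dummies plus a shared covariate block.  The Hessian is block structured --
    the dummy block is diagonal because intervals partition the rows -- so the
    Newton step is solved via the Schur complement on the covariate block.
    Cost per iteration is O(rows * n_cov) instead of O(rows * (n_cov + n_t)^2),
    which is what makes person-level bootstrap with full weight refitting
    affordable.

Both return coefficients at the (weighted) maximum likelihood; case weights
enter the log likelihood as frequency weights, so rescaling all weights leaves
the coefficients unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LogitFit", "PooledLogitFit", "fit_logit", "fit_pooled_logit"]

# linear predictors clipped here before expit; beyond +-30 the probability is
# within 1e-13 of {0,1} and exp() would overflow long before float64 does
_ETA_CLIP = 30.0


class ConvergenceError(RuntimeError):
    """Raised when Newton iterations fail to converge (e.g. separation)."""


def _expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))


@dataclass
class LogitFit:
    coef: np.ndarray
    n_iter: int
    converged: bool
    loglik: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _expit(X @ self.coef)


@dataclass
class PooledLogitFit:
    """Fit of logit p_it = alpha[t] + X_i(t) @ beta."""

    alpha: np.ndarray          # one intercept per modelled interval value
    beta: np.ndarray
    t_values: np.ndarray       # interval values alpha refers to, sorted
    n_iter: int
    converged: bool
    loglik: float

    def predict(self, t: np.ndarray, X: np.ndarray | None) -> np.ndarray:
        pos = np.searchsorted(self.t_values, t)
        ok = (pos < self.t_values.size) & (self.t_values[np.minimum(pos, self.t_values.size - 1)] == t)
        if not np.all(ok):
            raise ValueError("prediction requested for interval absent from fit")
        eta = self.alpha[pos]
        if X is not None and self.beta.size:
            eta = eta + X @ self.beta
        return _expit(eta)


def _check_inputs(y: np.ndarray, w: np.ndarray | None, n: int) -> np.ndarray:
    if y.shape[0] != n:
        raise ValueError("response length does not match design")
    if w is None:
        return np.ones(n)
    w = np.asarray(w, dtype=float)
    if w.shape[0] != n or np.any(w < 0):
        raise ValueError("weights must be non-negative and match the design")
    return w


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
    start: np.ndarray | None = None,
) -> LogitFit:
    """Weighted logistic MLE on a dense design (no implicit intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = _check_inputs(y, weights, X.shape[0])
    n, p = X.shape
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _expit(eta)
        ll = float(np.sum(w * (y * np.log(np.maximum(mu, 1e-300)) + (1 - y) * np.log(np.maximum(1 - mu, 1e-300)))))
        g = X.T @ (w * (y - mu))
        wpq = w * mu * (1 - mu)
        H = (X * wpq[:, None]).T @ X
        H[np.diag_indices_from(H)] += 1e-12
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - singular design
            raise ConvergenceError("singular Hessian; check for collinear covariates") from exc
        # step halving keeps the likelihood monotone near separation
        for _ in range(30):
            cand = beta + step
            mu_c = _expit(X @ cand)
            ll_c = float(np.sum(w * (y * np.log(np.maximum(mu_c, 1e-300)) + (1 - y) * np.log(np.maximum(1 - mu_c, 1e-300)))))
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        if np.max(np.abs(step)) < tol or abs(ll_c - ll_old) < tol * (abs(ll_old) + 1.0):
            return LogitFit(coef=beta, n_iter=it, converged=True, loglik=ll_c)
        ll_old = ll_c
    return LogitFit(coef=beta, n_iter=max_iter, converged=False, loglik=ll_old)


def fit_pooled_logit(
    t: np.ndarray,
    X: np.ndarray | None,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    tol: float = 1e-10,
    max_iter: int = 60,
    start: "PooledLogitFit | None" = None,
) -> PooledLogitFit:
    """Discrete-time logistic hazard model with one intercept per interval.

    Only intervals present in ``t`` receive an intercept; the model is
    saturated in time.  ``X`` may be ``None`` for a time-only (marginal)
    model.  ``start`` warm-starts Newton from a previous fit when its
    interval grid matches (bootstrap resamples converge in 2-3 iterations
    this way).
    """
    t = np.asarray(t)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    w = _check_inputs(y, weights, n)
    t_values, t_idx = np.unique(t, return_inverse=True)
    k = t_values.size
    if X is None or X.shape[1] == 0:
        Xc = np.empty((n, 0))
    else:
        Xc = np.asarray(X, dtype=float)
        if Xc.shape[0] != n:
            raise ValueError("covariate block does not match response length")
    p = Xc.shape[1]

    if start is not None and start.alpha.size == k and start.beta.size == p and np.array_equal(start.t_values, t_values):
        alpha, beta = start.alpha.copy(), start.beta.copy()
    else:
        alpha, beta = np.zeros(k), np.zeros(p)

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = alpha[t_idx] + (Xc @ beta if p else 0.0)
        mu = _expit(eta)
        resid = w * (y - mu)
        g_a = np.bincount(t_idx, weights=resid, minlength=k)
        wpq = w * mu * (1 - mu)
        D = np.bincount(t_idx, weights=wpq, minlength=k) + 1e-12
        if p:
            g_b = Xc.T @ resid
            B = np.empty((k, p))
            for j in range(p):
                B[:, j] = np.bincount(t_idx, weights=wpq * Xc[:, j], minlength=k)
            S = (Xc * wpq[:, None]).T @ Xc
            S[np.diag_indices_from(S)] += 1e-12
            # Schur complement on the covariate block
            BD = B / D[:, None]
            S_t = S - B.T @ BD
            rhs = g_b - BD.T @ g_a
            try:
                step_b = np.linalg.solve(S_t, rhs)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ConvergenceError("singular Hessian; check for collinear covariates") from exc
            step_a = (g_a - B @ step_b) / D
        else:
            step_b = np.zeros(0)
            step_a = g_a / D
        # likelihood-monotone damping
        ll = float(np.sum(w * (y * np.log(np.maximum(mu, 1e-300)) + (1 - y) * np.log(np.maximum(1 - mu, 1e-300)))))
        scale = 1.0
        for _ in range(30):
            a_c = alpha + scale * step_a
            b_c = beta + scale * step_b
            eta_c = a_c[t_idx] + (Xc @ b_c if p else 0.0)
            mu_c = _expit(eta_c)
            ll_c = float(np.sum(w * (y * np.log(np.maximum(mu_c, 1e-300)) + (1 - y) * np.log(np.maximum(1 - mu_c, 1e-300)))))
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        alpha, beta = a_c, b_c
        move = max(np.max(np.abs(scale * step_a)), np.max(np.abs(scale * step_b)) if p else 0.0)
        if move < tol or abs(ll_c - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            ll_old = ll_c
            break
        ll_old = ll_c
    return PooledLogitFit(alpha=alpha, beta=beta, t_values=t_values, n_iter=it, converged=converged, loglik=ll_old)
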