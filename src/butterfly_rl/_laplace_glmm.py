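"""Logistic mixed model with correlated random intercept + slopes, fitted by
Laplace-approximated marginal maximum likelihood.

Model, for participant j and trial i:

    y_ij ~ Bernoulli(sigmoid(x_ij . (beta + b_j))),   b_j ~ N(0, Sigma)

with x_ij = (1, regressors...). Sigma is parametrized by its Cholesky factor
(log-diagonal) so the outer optimization is unconstrained. The per-participant
integral over b_j is replaced by its Laplace approximation around the
conditional mode (found by Newton's method); this is the default strategy of
standard mixed-model software for binary outcomes.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def _sigmoid(eta):
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log1pexp(eta):
    out = np.empty_like(eta)
    hi = eta > 30
    out[hi] = eta[hi]
    out[~hi] = np.log1p(np.exp(eta[~hi]))
    return out


def _chol_from_theta(theta_cov, q):
    L = np.zeros((q, q))
    idx = 0
    for i in range(q):
        L[i, i] = np.exp(theta_cov[idx])
        idx += 1
    for i in range(1, q):
        for j in range(i):
            L[i, j] = theta_cov[idx]
            idx += 1
    return L


def _n_cov_params(q):
    return q + q * (q - 1) // 2


def _conditional_mode(X, y, beta, Sigma_inv, b0, max_iter=50, tol=1e-9):
    """Newton ascent of the per-participant joint log density in b."""
    b = b0.copy()
    for _ in range(max_iter):
        eta = X @ (beta + b)
        mu = _sigmoid(eta)
        grad = X.T @ (y - mu) - Sigma_inv @ b
        W = mu * (1.0 - mu)
        H = X.T @ (X * W[:, None]) + Sigma_inv
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped Newton: halve until the objective does not decrease
        f0 = (y @ eta - _log1pexp(eta).sum()) - 0.5 * b @ Sigma_inv @ b
        t = 1.0
        for _ in range(20):
            bn = b + t * step
            etan = X @ (beta + bn)
            fn = (y @ etan - _log1pexp(etan).sum()) - 0.5 * bn @ Sigma_inv @ bn
            if fn >= f0 - 1e-12:
                break
            t /= 2.0
        b = bn
        if np.max(np.abs(t * step)) < tol:
            break
    return b, H


def _marginal_negloglik(params, Xs, ys, q, b_cache):
    beta = params[:q]
    L = _chol_from_theta(params[q:], q)
    Sigma = L @ L.T
    try:
        Sigma_inv = np.linalg.inv(Sigma)
    except np.linalg.LinAlgError:
        return 1e10
    sign, logdet_Sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return 1e10
    total = 0.0
    for j, (X, y) in enumerate(zip(Xs, ys)):
        b_hat, H = _conditional_mode(X, y, beta, Sigma_inv, b_cache[j])
        b_cache[j] = b_hat
        eta = X @ (beta + b_hat)
        h = (y @ eta - _log1pexp(eta).sum()) - 0.5 * b_hat @ Sigma_inv @ b_hat
        sH, logdet_H = np.linalg.slogdet(H)
        if sH <= 0:
            return 1e10
        total += h - 0.5 * logdet_Sigma - 0.5 * logdet_H
    return -total


def fit_laplace_glmm(Xs: list[np.ndarray], ys: list[np.ndarray],
                     maxiter: int = 300) -> dict:
    """Fit the mixed logistic model; returns fixed effects, SEs, Sigma, modes.

    ``Xs``/``ys`` hold one design matrix (first column = intercept) and 0/1
    response vector per participant.
    """
    if len(Xs) < 2:
        raise ValueError("need >= 2 participants")
    q = Xs[0].shape[1]
    # start from pooled logistic regression for the fixed effects
    Xall = np.vstack(Xs)
    yall = np.concatenate(ys)
    beta0 = _pooled_logit(Xall, yall)
    x0 = np.concatenate([beta0, np.full(q, np.log(0.3)), np.zeros(_n_cov_params(q) - q)])
    b_cache = [np.zeros(q) for _ in Xs]

    res = optimize.minimize(
        _marginal_negloglik, x0, args=(Xs, ys, q, b_cache),
        method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"mixed-model optimization failed: {res.message}")

    theta = res.x
    beta = theta[:q]
    L = _chol_from_theta(theta[q:], q)
    Sigma = L @ L.T
    Sigma_inv = np.linalg.inv(Sigma)
    modes = np.array([
        _conditional_mode(X, y, beta, Sigma_inv, b_cache[j])[0]
        for j, (X, y) in enumerate(zip(Xs, ys))
    ])
    se = _fixed_effect_se(theta, Xs, ys, q, b_cache)
    return {
        "beta": beta,
        "se": se,
        "Sigma": Sigma,
        "random_modes": modes,
        "loglik": -res.fun,
        "converged": bool(res.success),
        "message": str(res.message),
        "n_params": len(theta),
    }


def _pooled_logit(X, y, max_iter=50):
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = _sigmoid(X @ beta)
        W = np.clip(mu * (1 - mu), 1e-10, None)
        H = X.T @ (X * W[:, None]) + 1e-8 * np.eye(X.shape[1])
        step = np.linalg.solve(H, X.T @ (y - mu))
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _fixed_effect_se(theta, Xs, ys, q, b_cache, h: float = 1e-4):
    """Wald SEs of the fixed effects, conditional on the variance parameters.

    Central-difference Hessian of the marginal deviance with respect to beta
    only, holding Sigma at its estimate — the standard mixed-model vcov.
    """
    hess = np.zeros((q, q))

    def f(beta_part):
        p = theta.copy()
        p[:q] = beta_part
        return _marginal_negloglik(p, Xs, ys, q, [b.copy() for b in b_cache])

    beta = theta[:q].copy()
    scale = np.maximum(np.abs(beta), 1.0) * h
    for i in range(q):
        for j in range(i, q):
            ei = np.zeros(q); ei[i] = scale[i]
            ej = np.zeros(q); ej[j] = scale[j]
            fpp = f(beta + ei + ej)
            fpm = f(beta + ei - ej)
            fmp = f(beta - ei + ej)
            fmm = f(beta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * scale[i] * scale[j])
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(q, np.nan)
    return se
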