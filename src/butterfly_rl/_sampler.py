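"""Adaptive Metropolis-within-Gibbs kernel for the hierarchical RL model.

The posterior factorizes as

    p(theta, coef, sigma | data) ∝
        prod_j L_j(theta_j) TN(theta_jk | m_jk, sigma_k, [lo_k, hi_k])
        * prior(coef) * prior(sigma)

with m_jk = X[j] . coef[k] (X is a column of ones, or [1, z_age, z_age^2] for
the age-regression variant) and TN a truncated normal including its
normalization, which matters because coef and sigma are sampled too.

One sweep = component-wise random-walk Metropolis updates of every individual
parameter (cost: one session likelihood per proposal), then of every group
coefficient and group sd (cost: n_participants truncated-normal terms, no
session likelihoods), then two joint "group moves" per free parameter that
de-funnel the hierarchy: a translation move shifting the group intercept and
every individual value by the same delta, and a scale move multiplying the
spread of the individual values around their group means together with the
group sd (accepted with the (n+1) log c Jacobian term). Without the group
moves, (mu, sigma) and the individual parameters drift along a ridge and
split-R-hat stalls above 1.05. Proposal scales adapt during warmup by
Robbins-Monro toward a 0.4 acceptance rate.
"""

import math

import numpy as np
from numba import njit

from ._kernels import session_loglik

SQRT2 = math.sqrt(2.0)
LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@njit(cache=False)
def _expand(model_code, free, out):
    # out = (alpha_pos, alpha_neg, beta, f)
    if model_code == 0:      # ab
        out[0] = free[0]; out[1] = free[0]; out[2] = free[1]; out[3] = 0.0
    elif model_code == 1:    # apanb
        out[0] = free[0]; out[1] = free[1]; out[2] = free[2]; out[3] = 0.0
    elif model_code == 2:    # apos0b
        out[0] = free[0]; out[1] = 0.0; out[2] = free[1]; out[3] = 0.0
    elif model_code == 3:    # abf
        out[0] = free[0]; out[1] = free[0]; out[2] = free[1]; out[3] = free[2]
    elif model_code == 4:    # apanbf
        out[0] = free[0]; out[1] = free[1]; out[2] = free[2]; out[3] = free[3]
    else:                    # apos0bf
        out[0] = free[0]; out[1] = 0.0; out[2] = free[1]; out[3] = free[2]


@njit(cache=False)
def _participant_loglik(model_code, free, stim, act, rew, miss, n_stimuli,
                        n_actions, scratch):
    p4 = np.empty(4)
    _expand(model_code, free, p4)
    total, _ = session_loglik(p4[0], p4[1], p4[2], p4[3], stim, act, rew, miss,
                              n_stimuli, n_actions, scratch)
    return total


@njit(cache=False)
def _tnorm_lp(x, m, s, lo, hi):
    if s <= 0.0:
        return -1e300
    za = 0.5 * (1.0 + math.erf((hi - m) / (s * SQRT2)))
    zb = 0.5 * (1.0 + math.erf((lo - m) / (s * SQRT2)))
    den = za - zb
    if den < 1e-300:
        return -1e300
    z = (x - m) / s
    return -0.5 * z * z - math.log(s) - LOG_SQRT_2PI - math.log(den)


@njit(cache=False)
def run_chain(seed, model_code, stim, act, rew, miss, ptr, n_stimuli, n_actions,
              X, lo, hi, coef_sd, sd_max, n_warmup_sweeps, n_keep, thin,
              adapt_interval, theta0, coef0, sigma0,
              theta_out, coef_out, sigma_out):
    """Run one chain; fills the *_out arrays with n_keep thinned draws."""
    np.random.seed(seed)
    n_part = ptr.shape[0] - 1
    K = lo.shape[0]
    P = X.shape[1]

    theta = theta0.copy()
    coef = coef0.copy()
    sigma = sigma0.copy()

    scratch = np.empty(stim.shape[0])
    ll = np.empty(n_part)
    for j in range(n_part):
        a, b = ptr[j], ptr[j + 1]
        ll[j] = _participant_loglik(model_code, theta[j], stim[a:b], act[a:b],
                                    rew[a:b], miss[a:b], n_stimuli, n_actions,
                                    scratch)
    m = np.empty((n_part, K))
    for j in range(n_part):
        for k in range(K):
            s = 0.0
            for p in range(P):
                s += X[j, p] * coef[k, p]
            m[j, k] = s

    scale_t = np.empty((n_part, K))
    for j in range(n_part):
        for k in range(K):
            scale_t[j, k] = 0.15 * (hi[k] - lo[k])
    scale_c = np.empty((K, P))
    scale_s = np.empty(K)
    for k in range(K):
        for p in range(P):
            scale_c[k, p] = 0.1 * (hi[k] - lo[k])
        scale_s[k] = 0.1 * sd_max[k]

    acc_t = np.zeros((n_part, K))
    acc_c = np.zeros((K, P))
    acc_s = np.zeros(K)

    scale_shift = np.empty((K, P))
    scale_scale = np.empty(K)
    for k in range(K):
        for p in range(P):
            scale_shift[k, p] = 0.05 * (hi[k] - lo[k])
        scale_scale[k] = 0.3
    acc_shift = np.zeros((K, P))
    acc_scale = np.zeros(K)
    ll_prop = np.empty(n_part)
    theta_prop = np.empty(n_part)
    m_prop = np.empty(n_part)

    # adaptive joint group move over v_k = (coef[k, :], log sigma[k]):
    # covariance learned during warmup, individuals recentered/rescaled
    D = P + 1
    joint_sum = np.zeros((K, D))
    joint_outer = np.zeros((K, D, D))
    joint_n = 0
    joint_chol = np.zeros((K, D, D))
    joint_ready = np.zeros(K, dtype=np.int64)
    joint_gamma = np.full(K, 0.6)
    acc_joint = np.zeros(K)
    dvec = np.empty(D)
    nvec = np.empty(D)

    total_sweeps = n_warmup_sweeps + n_keep * thin
    kept = 0
    prop = np.empty(K)
    for sweep in range(total_sweeps):
        # --- individual-level updates ---
        for j in range(n_part):
            a, b = ptr[j], ptr[j + 1]
            for k in range(K):
                x = theta[j, k]
                xp = x + scale_t[j, k] * np.random.normal()
                if xp < lo[k] or xp > hi[k]:
                    continue
                for kk in range(K):
                    prop[kk] = theta[j, kk]
                prop[k] = xp
                ll_new = _participant_loglik(model_code, prop, stim[a:b],
                                             act[a:b], rew[a:b], miss[a:b],
                                             n_stimuli, n_actions, scratch)
                delta = (ll_new - ll[j]
                         + _tnorm_lp(xp, m[j, k], sigma[k], lo[k], hi[k])
                         - _tnorm_lp(x, m[j, k], sigma[k], lo[k], hi[k]))
                if delta >= 0.0 or np.random.random() < math.exp(delta):
                    theta[j, k] = xp
                    ll[j] = ll_new
                    acc_t[j, k] += 1.0

        # --- group-level updates ---
        for k in range(K):
            for p in range(P):
                c = coef[k, p]
                cp = c + scale_c[k, p] * np.random.normal()
                if p == 0:
                    if cp < lo[k] or cp > hi[k]:
                        continue
                    dprior = 0.0
                else:
                    dprior = -0.5 * (cp * cp - c * c) / (coef_sd[k] * coef_sd[k])
                delta = dprior
                for j in range(n_part):
                    mp = m[j, k] + X[j, p] * (cp - c)
                    delta += (_tnorm_lp(theta[j, k], mp, sigma[k], lo[k], hi[k])
                              - _tnorm_lp(theta[j, k], m[j, k], sigma[k], lo[k], hi[k]))
                if delta >= 0.0 or np.random.random() < math.exp(delta):
                    for j in range(n_part):
                        m[j, k] += X[j, p] * (cp - c)
                    coef[k, p] = cp
                    acc_c[k, p] += 1.0

            s = sigma[k]
            sp = s + scale_s[k] * np.random.normal()
            if 1e-6 < sp <= sd_max[k]:
                delta = 0.0
                for j in range(n_part):
                    delta += (_tnorm_lp(theta[j, k], m[j, k], sp, lo[k], hi[k])
                              - _tnorm_lp(theta[j, k], m[j, k], s, lo[k], hi[k]))
                if delta >= 0.0 or np.random.random() < math.exp(delta):
                    sigma[k] = sp
                    acc_s[k] += 1.0

        # --- group translation moves: shift one group coefficient together
        # with every individual value along that covariate's direction ---
        for k in range(K):
            for p in range(P):
                d = scale_shift[k, p] * np.random.normal()
                cp = coef[k, p] + d
                if p == 0:
                    ok = lo[k] <= cp <= hi[k]
                    dprior = 0.0
                else:
                    ok = True
                    dprior = (-0.5 * (cp * cp - coef[k, p] * coef[k, p])
                              / (coef_sd[k] * coef_sd[k]))
                if ok:
                    for j in range(n_part):
                        theta_prop[j] = theta[j, k] + X[j, p] * d
                        if theta_prop[j] < lo[k] or theta_prop[j] > hi[k]:
                            ok = False
                            break
                if ok:
                    delta = dprior
                    for j in range(n_part):
                        a, b = ptr[j], ptr[j + 1]
                        for kk in range(K):
                            prop[kk] = theta[j, kk]
                        prop[k] = theta_prop[j]
                        ll_prop[j] = _participant_loglik(
                            model_code, prop, stim[a:b], act[a:b], rew[a:b],
                            miss[a:b], n_stimuli, n_actions, scratch)
                        delta += ll_prop[j] - ll[j]
                        delta += (_tnorm_lp(theta_prop[j], m[j, k] + X[j, p] * d,
                                            sigma[k], lo[k], hi[k])
                                  - _tnorm_lp(theta[j, k], m[j, k], sigma[k],
                                              lo[k], hi[k]))
                    if delta >= 0.0 or np.random.random() < math.exp(delta):
                        coef[k, p] = cp
                        for j in range(n_part):
                            theta[j, k] = theta_prop[j]
                            m[j, k] += X[j, p] * d
                            ll[j] = ll_prop[j]
                        acc_shift[k, p] += 1.0

        # --- group scale moves (rescale spread around means + group sd) ---
        for k in range(K):
            eps = scale_scale[k] * np.random.normal()
            c = math.exp(eps)
            sp = c * sigma[k]
            ok = 1e-6 < sp <= sd_max[k]
            if ok:
                for j in range(n_part):
                    theta_prop[j] = m[j, k] + c * (theta[j, k] - m[j, k])
                    if theta_prop[j] < lo[k] or theta_prop[j] > hi[k]:
                        ok = False
                        break
            if ok:
                delta = (n_part + 1.0) * eps
                for j in range(n_part):
                    a, b = ptr[j], ptr[j + 1]
                    for kk in range(K):
                        prop[kk] = theta[j, kk]
                    prop[k] = theta_prop[j]
                    ll_prop[j] = _participant_loglik(
                        model_code, prop, stim[a:b], act[a:b], rew[a:b],
                        miss[a:b], n_stimuli, n_actions, scratch)
                    delta += ll_prop[j] - ll[j]
                    delta += (_tnorm_lp(theta_prop[j], m[j, k], sp, lo[k], hi[k])
                              - _tnorm_lp(theta[j, k], m[j, k], sigma[k], lo[k], hi[k]))
                if delta >= 0.0 or np.random.random() < math.exp(delta):
                    sigma[k] = sp
                    for j in range(n_part):
                        theta[j, k] = theta_prop[j]
                        ll[j] = ll_prop[j]
                    acc_scale[k] += 1.0

        # --- adaptive joint group moves ---
        if sweep >= n_warmup_sweeps // 3:
            for k in range(K):
                joint_sum[k, P] += math.log(sigma[k])
                for p in range(P):
                    joint_sum[k, p] += coef[k, p]
                for a_ in range(D):
                    va = math.log(sigma[k]) if a_ == P else coef[k, a_]
                    for b_ in range(D):
                        vb = math.log(sigma[k]) if b_ == P else coef[k, b_]
                        joint_outer[k, a_, b_] += va * vb
            joint_n += 1

        for k in range(K):
            if joint_ready[k] == 0:
                continue
            for i in range(D):
                nvec[i] = np.random.normal()
            for i in range(D):
                s_ = 0.0
                for jj in range(i + 1):
                    s_ += joint_chol[k, i, jj] * nvec[jj]
                dvec[i] = joint_gamma[k] * s_
            sp = sigma[k] * math.exp(dvec[P])
            ok = 1e-8 < sp <= sd_max[k]
            mu0 = coef[k, 0] + dvec[0]
            if mu0 < lo[k] or mu0 > hi[k]:
                ok = False
            if ok:
                ratio = sp / sigma[k]
                for j in range(n_part):
                    shift = 0.0
                    for p in range(P):
                        shift += X[j, p] * dvec[p]
                    m_prop[j] = m[j, k] + shift
                    theta_prop[j] = m_prop[j] + ratio * (theta[j, k] - m[j, k])
                    if theta_prop[j] < lo[k] or theta_prop[j] > hi[k]:
                        ok = False
                        break
            if ok:
                delta = (n_part + 1.0) * dvec[P]
                for p in range(1, P):
                    cp = coef[k, p] + dvec[p]
                    delta += (-0.5 * (cp * cp - coef[k, p] * coef[k, p])
                              / (coef_sd[k] * coef_sd[k]))
                for j in range(n_part):
                    a, b = ptr[j], ptr[j + 1]
                    for kk in range(K):
                        prop[kk] = theta[j, kk]
                    prop[k] = theta_prop[j]
                    ll_prop[j] = _participant_loglik(
                        model_code, prop, stim[a:b], act[a:b], rew[a:b],
                        miss[a:b], n_stimuli, n_actions, scratch)
                    delta += ll_prop[j] - ll[j]
                    delta += (_tnorm_lp(theta_prop[j], m_prop[j], sp, lo[k], hi[k])
                              - _tnorm_lp(theta[j, k], m[j, k], sigma[k], lo[k], hi[k]))
                if delta >= 0.0 or np.random.random() < math.exp(delta):
                    sigma[k] = sp
                    for p in range(P):
                        coef[k, p] += dvec[p]
                    for j in range(n_part):
                        theta[j, k] = theta_prop[j]
                        m[j, k] = m_prop[j]
                        ll[j] = ll_prop[j]
                    acc_joint[k] += 1.0

        # --- warmup adaptation ---
        if sweep < n_warmup_sweeps and (sweep + 1) % adapt_interval == 0:
            inv = 1.0 / adapt_interval
            for j in range(n_part):
                for k in range(K):
                    rate = acc_t[j, k] * inv
                    scale_t[j, k] *= math.exp(rate - 0.4)
                    w = hi[k] - lo[k]
                    if scale_t[j, k] > w:
                        scale_t[j, k] = w
                    if scale_t[j, k] < 1e-6 * w:
                        scale_t[j, k] = 1e-6 * w
                    acc_t[j, k] = 0.0
            for k in range(K):
                for p in range(P):
                    rate = acc_c[k, p] * inv
                    scale_c[k, p] *= math.exp(rate - 0.4)
                    acc_c[k, p] = 0.0
                rate = acc_s[k] * inv
                scale_s[k] *= math.exp(rate - 0.4)
                acc_s[k] = 0.0
                for p in range(P):
                    rate = acc_shift[k, p] * inv
                    scale_shift[k, p] *= math.exp(rate - 0.4)
                    acc_shift[k, p] = 0.0
                rate = acc_scale[k] * inv
                scale_scale[k] = min(scale_scale[k] * math.exp(rate - 0.4), 2.0)
                acc_scale[k] = 0.0
                if joint_ready[k] == 1:
                    rate = acc_joint[k] * inv
                    joint_gamma[k] = min(joint_gamma[k] * math.exp(rate - 0.25), 3.0)
                acc_joint[k] = 0.0

            # refresh the joint-move covariance once enough samples accrued
            if joint_n >= max(200, 2 * adapt_interval):
                for k in range(K):
                    covm = np.empty((D, D))
                    for a_ in range(D):
                        for b_ in range(D):
                            covm[a_, b_] = (joint_outer[k, a_, b_] / joint_n
                                            - (joint_sum[k, a_] / joint_n)
                                            * (joint_sum[k, b_] / joint_n))
                    for a_ in range(D):
                        covm[a_, a_] += 1e-8 + 1e-3 * covm[a_, a_]
                    okc = True
                    for a_ in range(D):
                        if not np.isfinite(covm[a_, a_]) or covm[a_, a_] <= 0:
                            okc = False
                    if okc:
                        joint_chol[k] = np.linalg.cholesky(covm)
                        joint_ready[k] = 1

        # --- storage ---
        if sweep >= n_warmup_sweeps and (sweep - n_warmup_sweeps) % thin == thin - 1:
            for j in range(n_part):
                for k in range(K):
                    theta_out[kept, j, k] = theta[j, k]
            for k in range(K):
                for p in range(P):
                    coef_out[kept, k, p] = coef[k, p]
                sigma_out[kept, k] = sigma[k]
            kept += 1
    return kept


@njit(cache=False)
def pointwise_loglik_draws(model_code, theta_draws, stim, act, rew, miss, ptr,
                           n_stimuli, n_actions, n_points, out):
    """Per-trial log-likelihood matrix (draws x non-missing trials) from
    individual-parameter draws. ``theta_draws``: (n_draws, n_part, K)."""
    n_draws = theta_draws.shape[0]
    n_part = ptr.shape[0] - 1
    p4 = np.empty(4)
    scratch = np.empty(stim.shape[0])
    for d in range(n_draws):
        col = 0
        for j in range(n_part):
            a, b = ptr[j], ptr[j + 1]
            _expand(model_code, theta_draws[d, j], p4)
            total, k = session_loglik(p4[0], p4[1], p4[2], p4[3], stim[a:b],
                                      act[a:b], rew[a:b], miss[a:b], n_stimuli,
                                      n_actions, scratch)
            for i in range(k):
                out[d, col + i] = scratch[i]
            col += k
    return out
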