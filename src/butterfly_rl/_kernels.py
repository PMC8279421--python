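"""Numba kernels for the trial-loop likelihood and agent simulation.

These are the hot inner loops shared by MLE, hierarchical MCMC, and the
Monte-Carlo validation sweeps. Semantics per trial: evaluate the softmax choice
probability on the pre-update Q table, apply the delta rule to the chosen
(stimulus, action) pair, then decay every *other* pair toward 0.5. Forgetting
is applied on missing trials too (it models the passage of trials, not choice),
while the delta update and the likelihood term are skipped there.
"""

import math

import numpy as np
from numba import njit


@njit(cache=False)
def seed(value):
    # numba keeps its own RNG state, distinct from NumPy's global one
    np.random.seed(value)


@njit(cache=False)
def softmax_row(q_row, beta, out):
    m = q_row[0]
    for i in range(1, q_row.shape[0]):
        if q_row[i] > m:
            m = q_row[i]
    z = 0.0
    for i in range(q_row.shape[0]):
        out[i] = math.exp(beta * (q_row[i] - m))
        z += out[i]
    for i in range(q_row.shape[0]):
        out[i] /= z


@njit(cache=False)
def session_loglik(alpha_pos, alpha_neg, beta, f, stim, act, rew, missing,
                   n_stimuli, n_actions, pointwise):
    """Total choice log-likelihood of one session; fills ``pointwise`` for
    non-missing trials in order. Returns (total, n_used)."""
    q = np.full((n_stimuli, n_actions), 0.5)
    p = np.empty(n_actions)
    total = 0.0
    k = 0
    for t in range(stim.shape[0]):
        s = stim[t]
        if missing[t] == 0:
            a = act[t]
            softmax_row(q[s], beta, p)
            ll = math.log(p[a])
            pointwise[k] = ll
            k += 1
            total += ll
            rpe = rew[t] - q[s, a]
            alpha = alpha_pos if rpe > 0.0 else alpha_neg
            q[s, a] += alpha * rpe
            if f > 0.0:
                for ss in range(n_stimuli):
                    for aa in range(n_actions):
                        if not (ss == s and aa == a):
                            q[ss, aa] = (1.0 - f) * q[ss, aa] + f * 0.5
        else:
            if f > 0.0:
                for ss in range(n_stimuli):
                    for aa in range(n_actions):
                        q[ss, aa] = (1.0 - f) * q[ss, aa] + f * 0.5
    return total, k


@njit(cache=False)
def simulate_session(alpha_pos, alpha_neg, beta, f, stim, correct_action,
                     reward_draw, n_stimuli, n_actions, actions, rewards):
    """Simulate an RL agent through a pre-drawn design (numba RNG; seed first)."""
    q = np.full((n_stimuli, n_actions), 0.5)
    p = np.empty(n_actions)
    for t in range(stim.shape[0]):
        s = stim[t]
        softmax_row(q[s], beta, p)
        u = np.random.random()
        a = n_actions - 1
        c = 0.0
        for i in range(n_actions):
            c += p[i]
            if u < c:
                a = i
                break
        is_correct = 1 if a == correct_action[s] else 0
        r = 1 if is_correct == reward_draw[t] else 0
        actions[t] = a
        rewards[t] = r
        rpe = r - q[s, a]
        alpha = alpha_pos if rpe > 0.0 else alpha_neg
        q[s, a] += alpha * rpe
        if f > 0.0:
            for ss in range(n_stimuli):
                for aa in range(n_actions):
                    if not (ss == s and aa == a):
                        q[ss, aa] = (1.0 - f) * q[ss, aa] + f * 0.5


@njit(cache=False)
def mean_accuracy_sweep(alpha_pos, alpha_neg, beta, f, stim, correct_action,
                        reward_draw, n_stimuli, n_actions, n_sims, seed):
    """Mean fraction of correct choices over ``n_sims`` simulated sessions."""
    np.random.seed(seed)
    n = stim.shape[0]
    actions = np.empty(n, dtype=np.int64)
    rewards = np.empty(n, dtype=np.int64)
    acc = 0.0
    for _ in range(n_sims):
        simulate_session(alpha_pos, alpha_neg, beta, f, stim, correct_action,
                         reward_draw, n_stimuli, n_actions, actions, rewards)
        c = 0
        for t in range(n):
            if actions[t] == correct_action[stim[t]]:
                c += 1
        acc += c / n
    return acc / n_sims
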