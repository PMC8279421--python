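"""Independent brute-force reference implementations used only by tests.

Deliberately naive (dicts, explicit loops, no vectorization, no shared code
with the package's kernels) so they can serve as oracles for the fast paths.
"""

import math

import numpy as np


def naive_session_loglik(alpha_pos, alpha_neg, beta, f, trial_data,
                         n_stimuli, n_actions):
    """Pure-python trial loop over dict-of-dicts Q values."""
    q = {(s, a): 0.5 for s in range(n_stimuli) for a in range(n_actions)}
    total = 0.0
    pointwise = []
    for t in range(trial_data.n_trials):
        s = int(trial_data.stimulus[t])
        if int(trial_data.missing[t]) == 0:
            a = int(trial_data.action[t])
            r = int(trial_data.reward[t])
            exps = [math.exp(beta * q[(s, i)]) for i in range(n_actions)]
            p = exps[a] / sum(exps)
            total += math.log(p)
            pointwise.append(math.log(p))
            rpe = r - q[(s, a)]
            lr = alpha_pos if rpe > 0 else alpha_neg
            q[(s, a)] = q[(s, a)] + lr * rpe
            for key in q:
                if key != (s, a):
                    q[key] = (1 - f) * q[key] + f * 0.5
        else:
            for key in q:
                q[key] = (1 - f) * q[key] + f * 0.5
    return total, pointwise


def naive_waic(loglik_matrix):
    """Direct transcription of the WAIC formula, one datapoint at a time."""
    loglik_matrix = np.asarray(loglik_matrix, float)
    n_draws, n_points = loglik_matrix.shape
    lppd = 0.0
    p_waic = 0.0
    for i in range(n_points):
        col = loglik_matrix[:, i]
        lppd += math.log(np.mean([math.exp(v) for v in col]))
        mean = sum(col) / n_draws
        p_waic += sum((v - mean) ** 2 for v in col) / (n_draws - 1) if n_draws > 1 else 0.0
    return -2.0 * (lppd - p_waic), lppd, p_waic


def naive_regressors(trial_data):
    """O(n^2) backward scan for reward history r and delay d per trial."""
    rows = []
    for t in range(trial_data.n_trials):
        if int(trial_data.missing[t]) == 1:
            continue
        s = int(trial_data.stimulus[t])
        r = 0
        for u in range(t):
            if (int(trial_data.missing[u]) == 0 and int(trial_data.stimulus[u]) == s
                    and int(trial_data.reward[u]) == 1):
                r += 1
        d = None
        for u in range(t - 1, -1, -1):
            if (int(trial_data.missing[u]) == 0 and int(trial_data.stimulus[u]) == s
                    and int(trial_data.reward[u]) == 1):
                d = t - u - 1  # trials strictly between the two encounters
                break
        rows.append((t, r, d))
    return rows
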