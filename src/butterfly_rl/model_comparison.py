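"""Model comparison: WAIC for hierarchical fits, BIC for per-subject fits,
and a count-based model-identifiability matrix.

The pointwise unit for WAIC is one non-missing trial: the likelihood
factorizes by trial, and pointwise log-likelihoods are computed per trial
during sampling. Lower WAIC / BIC is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rl_models import get_model


@dataclass
class WaicResult:
    waic: float
    lppd: float
    p_waic: float
    se: float
    n_points: int


def waic(pointwise_loglik_draws: np.ndarray) -> WaicResult:
    """WAIC from a (draws x datapoints) matrix of pointwise log-likelihoods.

    lppd_i = log mean_d exp(ll_di) (computed stably); p_waic_i = var_d ll_di;
    WAIC = -2 * sum_i (lppd_i - p_waic_i). The pointwise standard error uses
    the usual sqrt(n * var_i) of the pointwise WAIC contributions.
    """
    ll = np.asarray(pointwise_loglik_draws, dtype=float)
    if ll.ndim != 2:
        raise ValueError("expected a draws x datapoints matrix")
    if not np.isfinite(ll).all():
        raise ValueError("non-finite log-likelihood entries")
    n_draws, n_points = ll.shape
    m = ll.max(axis=0)
    lppd_i = m + np.log(np.mean(np.exp(ll - m), axis=0))
    p_waic_i = ll.var(axis=0, ddof=1) if n_draws > 1 else np.zeros(n_points)
    elpd_i = lppd_i - p_waic_i
    waic_val = -2.0 * elpd_i.sum()
    se = 2.0 * np.sqrt(n_points * elpd_i.var(ddof=1)) if n_points > 1 else 0.0
    return WaicResult(waic=float(waic_val), lppd=float(lppd_i.sum()),
                      p_waic=float(p_waic_i.sum()), se=float(se),
                      n_points=n_points)


def bic(max_loglik: float, k_free_params: int, n_datapoints: int) -> float:
    """k ln n - 2 max-log-likelihood; n = non-missing trials."""
    if n_datapoints < 1:
        raise ValueError("n_datapoints must be >= 1")
    return k_free_params * np.log(n_datapoints) - 2.0 * max_loglik


def compare(fits_by_model: dict[str, np.ndarray]) -> pd.DataFrame:
    """ComparisonTable from pointwise log-likelihood matrices per model.

    All matrices must cover the identical datapoints. Returns one row per
    model with WAIC, lppd, p_waic, delta WAIC vs the best, and a winner flag;
    ties break toward the model with fewer free parameters.
    """
    if not fits_by_model:
        raise ValueError("no fits supplied")
    n_points = {m: ll.shape[1] for m, ll in fits_by_model.items()}
    if len(set(n_points.values())) != 1:
        raise ValueError(f"datapoint counts differ across models: {n_points}")
    rows = []
    for name, ll in fits_by_model.items():
        w = waic(ll)
        rows.append(dict(model=name, waic=w.waic, lppd=w.lppd, p_waic=w.p_waic,
                         se=w.se, n_free=get_model(name).n_free))
    table = pd.DataFrame(rows)
    table["delta_waic"] = table["waic"] - table["waic"].min()
    winner_idx = table.sort_values(["delta_waic", "n_free"]).index[0]
    table["winner"] = False
    table.loc[winner_idx, "winner"] = True
    return table.drop(columns="n_free")


def compare_bic(bic_by_model: dict[str, np.ndarray],
                reference: str = "apos0bf") -> pd.DataFrame:
    """Per-participant delta BIC vs a reference model (flat-fit comparison)."""
    ref = np.asarray(bic_by_model[reference], float)
    rows = []
    for name, b in bic_by_model.items():
        b = np.asarray(b, float)
        rows.append(dict(model=name, mean_bic=b.mean(),
                         mean_delta_bic=(b - ref).mean(),
                         wins=int((b <= np.min(np.stack(
                             [np.asarray(v) for v in bic_by_model.values()]),
                             axis=0) + 1e-12).sum())))
    return pd.DataFrame(rows)


def identifiability_matrix(model_names, gen_laws, n_replicates: int,
                           n_participants: int, rng: np.random.Generator,
                           fit_fn=None, design_kwargs=None) -> pd.DataFrame:
    """Generate-and-recover at the model level: rows = generating model,
    columns = fraction of replicates each candidate model won (by the
    criterion implemented in ``fit_fn``).

    ``fit_fn(model_name, cohort, rng) -> criterion`` (lower = better) defaults
    to per-subject MLE + summed BIC, the cheap flat criterion.
    """
    from .hierarchical_fit import fit_mle_per_subject
    from .synthetic_cohort import make_recovery_grid

    model_names = list(model_names)
    if len(model_names) < 2:
        raise ValueError("need >= 2 models")

    if fit_fn is None:
        def fit_fn(name, cohort, rng):
            spec = get_model(name)
            total = 0.0
            for td in cohort.sessions:
                _, ll = fit_mle_per_subject(
                    spec, td, n_restarts=4, seed=int(rng.integers(0, 2**31 - 1)))
                n = int((td.missing == 0).sum())
                total += bic(ll, spec.n_free, n)
            return total

    counts = pd.DataFrame(0.0, index=model_names, columns=model_names)
    for gen_name in model_names:
        for _ in range(n_replicates):
            cohort = make_recovery_grid(
                gen_name, grid=None, n_per_cell=n_participants, rng=rng,
                draw_laws=gen_laws, design_kwargs=design_kwargs)
            scores = {}
            for cand in model_names:
                try:
                    scores[cand] = fit_fn(cand, cohort, rng)
                except RuntimeError:
                    scores[cand] = np.inf  # recorded, not fatal
            best = min(scores, key=lambda c: (scores[c], get_model(c).n_free))
            counts.loc[gen_name, best] += 1
    return counts / n_replicates
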