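"""Generate-and-recover, posterior-predictive checks, age-coefficient
recovery, and parameter-performance sweeps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .hierarchical_fit import (AgeRegressionSpec, PriorSpec, SamplerConfig,
                               credible_interval, fit_hierarchical,
                               fit_hierarchical_age_regression,
                               fit_mle_per_subject)
from .rl_models import get_model
from .synthetic_cohort import CohortData, GroupConfig, generate_cohort
from .task_env import make_design


@dataclass
class RecoveryReport:
    """Per-parameter paired true/recovered values and agreement statistics."""

    per_param: dict  # name -> dict(true, recovered, pearson, spearman, bias, rmse)

    def correlation(self, name: str, kind: str = "pearson") -> float:
        return self.per_param[name][kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            dict(param=k, pearson=v["pearson"], spearman=v["spearman"],
                 bias=v["bias"], rmse=v["rmse"])
            for k, v in self.per_param.items()
        ])


def _pair_stats(true, rec) -> dict:
    true = np.asarray(true, float)
    rec = np.asarray(rec, float)
    if np.std(true) == 0 or np.std(rec) == 0:
        pear = spear = np.nan  # correlation undefined for degenerate spread
    else:
        pear = float(stats.pearsonr(true, rec)[0])
        spear = float(stats.spearmanr(true, rec)[0])
    return dict(true=true, recovered=rec, pearson=pear, spearman=spear,
                bias=float(np.mean(rec - true)),
                rmse=float(np.sqrt(np.mean((rec - true) ** 2))))


def generate_and_recover(model_spec, gen_config: GroupConfig, fit_mode: str,
                         rng: np.random.Generator,
                         sampler_config: SamplerConfig | None = None,
                         prior_spec: PriorSpec = PriorSpec(),
                         n_restarts: int = 8) -> RecoveryReport:
    """Simulate a cohort with known parameters, refit, and score agreement.

    ``fit_mode``: "hierarchical" (recovered value = posterior mean) or "mle"
    (best-restart optimum).
    """
    model_spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    cohort = generate_cohort(gen_config, model_spec, rng)
    true = cohort.true_params(model_spec)

    if fit_mode == "hierarchical":
        cfg = sampler_config or SamplerConfig(
            n_chains=2, n_warmup=600, n_samples=600, thin=3,
            seed=int(rng.integers(0, 2**31 - 1)))
        post = fit_hierarchical(model_spec, cohort, prior_spec, cfg)
        recovered = post.individual_means()
    elif fit_mode == "mle":
        recovered = np.array([
            fit_mle_per_subject(model_spec, td, n_restarts=n_restarts,
                                beta_max=prior_spec.beta_max,
                                seed=int(rng.integers(0, 2**31 - 1)))[0]
            for td in cohort.sessions
        ])
        recovered = np.array([[getattr(p, name) for name in model_spec.free_params]
                              for p in recovered])
    else:
        raise ValueError("fit_mode must be 'hierarchical' or 'mle'")

    report = {}
    for k, name in enumerate(model_spec.free_params):
        report[name] = _pair_stats(true[:, k], recovered[:, k])
    return RecoveryReport(per_param=report)


def recover_age_coefficients(model_spec, age_spec: AgeRegressionSpec,
                             gen_config: GroupConfig, n_replicates: int,
                             rng: np.random.Generator,
                             sampler_config: SamplerConfig | None = None,
                             target: str = "alpha_pos") -> pd.DataFrame:
    """Simulate cohorts with known age-regression coefficients, refit with the
    age-regression model, and report CI coverage and sign detection.

    Returns one row per replicate with the true linear coefficient (on the
    z-age scale), its posterior mean, the 95% CI, coverage, and whether zero
    is excluded.
    """
    model_spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    rows = []
    for rep in range(n_replicates):
        cohort = generate_cohort(gen_config, model_spec,
                                 np.random.default_rng(int(rng.integers(0, 2**31 - 1))))
        cfg = sampler_config or SamplerConfig(
            n_chains=2, n_warmup=500, n_samples=500, thin=3,
            seed=int(rng.integers(0, 2**31 - 1)))
        post = fit_hierarchical_age_regression(model_spec, cohort, age_spec,
                                               sampler_config=cfg)
        ci = credible_interval(post, f"coef_{target}_linear")
        true_lin = gen_config.laws[target].linear
        rows.append(dict(replicate=rep, true_linear=true_lin,
                         post_mean=ci["mean"], ci_low=ci["low"],
                         ci_high=ci["high"],
                         covered=bool(ci["low"] <= true_lin <= ci["high"]),
                         excludes_zero=ci["excludes_zero"]))
    return pd.DataFrame(rows)


def posterior_predictive(fitted_params: np.ndarray, model_spec, cohort: CohortData,
                         n_sims_per_participant: int = 100,
                         rng: np.random.Generator | None = None,
                         n_blocks: int = 4) -> dict:
    """Simulate sessions at fitted (posterior-mean) parameters and aggregate
    block-accuracy learning curves against the observed ones.

    ``fitted_params``: (n_participants, n_free). Returns observed and
    simulated per-participant block curves plus the cohort-mean overlay and a
    per-block simulation envelope.
    """
    from .behavior import summarize

    model_spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    rng = rng or np.random.default_rng(0)
    if len(fitted_params) != cohort.n:
        raise ValueError("one parameter vector per participant required")
    n = cohort.n
    obs = np.vstack([summarize(td, n_blocks).block_accuracy for td in cohort.sessions])
    sim = np.empty((n, n_sims_per_participant, n_blocks))
    from .rl_models import simulate_agent
    for j in range(n):
        params = model_spec.expand(fitted_params[j])
        design = cohort.designs[j]
        for s in range(n_sims_per_participant):
            td = simulate_agent(params, model_spec, design, rng)
            sim[j, s] = summarize(td, n_blocks).block_accuracy
    sim_mean = sim.mean(axis=1)
    lo, hi = np.quantile(sim.mean(axis=0), [0.025, 0.975], axis=0)
    return dict(observed=obs, simulated=sim_mean,
                observed_curve=obs.mean(axis=0),
                simulated_curve=sim_mean.mean(axis=0),
                envelope_low=lo, envelope_high=hi,
                n_sims=n_sims_per_participant)


def performance_sweep(model_spec, param_grid: dict, n_sims_per_cell: int,
                      rng: np.random.Generator,
                      fixed: dict | None = None,
                      design_kwargs: dict | None = None) -> pd.DataFrame:
    """Monte-Carlo mean overall accuracy over a parameter grid.

    ``param_grid`` maps up to two free-parameter names to value arrays (the
    Cartesian product is swept); remaining free parameters come from
    ``fixed``. Marks the per-column local maxima (over the first grid axis)
    and the global maximum.
    """
    model_spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    if not param_grid:
        raise ValueError("empty grid")
    fixed = fixed or {}
    design_kwargs = design_kwargs or {}
    names = list(param_grid)
    axes = [np.asarray(param_grid[n], float) for n in names]
    mesh = np.meshgrid(*axes, indexing="ij")
    cells = np.stack([m.ravel() for m in mesh], axis=1)

    rows = []
    for cell in cells:
        d = {p: fixed.get(p, 0.0) for p in model_spec.free_params}
        d.update(zip(names, cell))
        params = model_spec.expand([d[p] for p in model_spec.free_params])
        design = make_design(seed=int(rng.integers(0, 2**31 - 1)), **design_kwargs)
        acc = _kernels.mean_accuracy_sweep(
            params.alpha_pos, params.alpha_neg, params.beta, params.f,
            design.stimulus_sequence.astype(np.int64),
            design.correct_action.astype(np.int64),
            design.reward_draw.astype(np.int64),
            design.n_stimuli, design.n_actions, n_sims_per_cell,
            int(rng.integers(0, 2**31 - 1)))
        row = dict(zip(names, cell))
        row["accuracy"] = acc
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(names) == 2:
        df["column_max"] = False
        for _, grp in df.groupby(names[1]):
            df.loc[grp["accuracy"].idxmax(), "column_max"] = True
    df["global_max"] = False
    df.loc[df["accuracy"].idxmax(), "global_max"] = True
    return df
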