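"""Hierarchical Bayesian estimation of RL parameters, and per-subject MLE.

Individual parameters are drawn from truncated-normal group distributions
(group mean and sd estimated jointly; uniform hyperpriors over the natural
parameter ranges), optionally replacing the group mean with a linear or
quadratic regression on z-scored age. Sampling uses an authored adaptive
Metropolis-within-Gibbs kernel (see ``_sampler``); convergence is judged by
the split-R-hat and effective-sample-size criteria (max R-hat < 1.05, min ESS
> 25 x number of chains), computed with arviz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import _sampler
from .rl_models import MODELS, ModelSpec, Params, get_model, session_loglik
from .synthetic_cohort import CohortData
from .task_env import TrialData

MODEL_CODES = {name: i for i, name in enumerate(MODELS)}


@dataclass(frozen=True)
class PriorSpec:
    """Hyperprior bounds. Unit-interval parameters live on [0, 1]; beta on
    [0, beta_max]. Group sds are uniform on (0, sd_max]; age-regression
    coefficients get zero-mean normal priors with sd = coef_sd_frac x range."""

    beta_max: float = 30.0
    sd_max_unit: float = 1.0
    sd_max_beta: float = 10.0
    coef_sd_frac: float = 0.5

    def bounds(self, model_spec: ModelSpec):
        lo = np.zeros(model_spec.n_free)
        hi = np.array([self.beta_max if p == "beta" else 1.0
                       for p in model_spec.free_params])
        sd_max = np.array([self.sd_max_beta if p == "beta" else self.sd_max_unit
                           for p in model_spec.free_params])
        coef_sd = self.coef_sd_frac * (hi - lo)
        if np.any(hi <= lo) or np.any(sd_max <= 0):
            raise ValueError("impossible prior bounds")
        return lo, hi, sd_max, coef_sd


@dataclass(frozen=True)
class AgeRegressionSpec:
    """Regress the group mean of each target parameter on z-scored age."""

    targets: tuple = ("alpha_pos", "beta", "f")
    degree: int = 1

    def __post_init__(self):
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")


@dataclass(frozen=True)
class SamplerConfig:
    """``n_samples`` retained draws per chain after thinning; warmup counts
    raw sweeps before any draw is kept."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 4000
    thin: int = 5
    adapt_interval: int = 50
    seed: int = 0

    @property
    def warmup_sweeps(self) -> int:
        return self.n_warmup * self.thin


COEF_NAMES = ("intercept", "linear", "quadratic")


@dataclass
class PosteriorSamples:
    """MCMC draws: individual params (chain, draw, participant, free-param),
    group coefficients (chain, draw, free-param, coef), group sds, plus
    everything needed to recompute pointwise log-likelihoods."""

    model: ModelSpec
    theta: np.ndarray
    coef: np.ndarray
    sigma: np.ndarray
    participant_ids: list
    free_params: tuple
    coef_names: tuple
    age_mean: float | None = None
    age_sd: float | None = None
    divergences: int = 0
    _packed: tuple = field(default=None, repr=False)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    def individual_means(self) -> np.ndarray:
        """(n_participants, n_free) posterior means."""
        return self.theta.mean(axis=(0, 1))

    def draws(self, quantity: str) -> np.ndarray:
        """Flat draws of a named quantity.

        Names: ``mu_<param>`` / ``coef_<param>_<intercept|linear|quadratic>``,
        ``sigma_<param>``, ``theta_<param>[j]``.
        """
        for k, pname in enumerate(self.free_params):
            if quantity == f"sigma_{pname}":
                return self.sigma[:, :, k].ravel()
            if quantity == f"mu_{pname}":
                return self.coef[:, :, k, 0].ravel()
            for p, cname in enumerate(self.coef_names):
                if quantity == f"coef_{pname}_{cname}":
                    return self.coef[:, :, k, p].ravel()
            prefix = f"theta_{pname}["
            if quantity.startswith(prefix) and quantity.endswith("]"):
                j = int(quantity[len(prefix):-1])
                return self.theta[:, :, j, k].ravel()
        raise KeyError(f"unknown quantity {quantity!r}")

    def to_inference_data(self):
        import arviz as az

        posterior = {}
        for k, pname in enumerate(self.free_params):
            posterior[pname] = self.theta[:, :, :, k]
            posterior[f"sigma_{pname}"] = self.sigma[:, :, k]
            for p, cname in enumerate(self.coef_names):
                posterior[f"coef_{pname}_{cname}"] = self.coef[:, :, k, p]
        return az.from_dict(posterior=posterior)

    def pointwise_loglik(self, draw_stride: int = 1) -> np.ndarray:
        """(n_kept_draws, n_nonmissing_trials) matrix for WAIC."""
        (stim, act, rew, miss, ptr, n_stimuli, n_actions) = self._packed
        flat = self.theta.reshape(-1, *self.theta.shape[2:])[::draw_stride]
        n_points = int((miss == 0).sum())
        out = np.empty((flat.shape[0], n_points))
        _sampler.pointwise_loglik_draws(
            MODEL_CODES[self.model.name], flat, stim, act, rew, miss, ptr,
            n_stimuli, n_actions, n_points, out)
        return out


def _pack_cohort(cohort: CohortData):
    stim, act, rew, miss = [], [], [], []
    ptr = [0]
    for td in cohort.sessions:
        td.validate()
        stim.append(td.stimulus)
        act.append(np.where(td.missing == 1, 0, td.action))
        rew.append(np.where(td.missing == 1, 0, td.reward))
        miss.append(td.missing)
        ptr.append(ptr[-1] + td.n_trials)
    n_stimuli = cohort.designs[0].n_stimuli if cohort.designs else int(
        max(s.max() for s in stim)) + 1
    n_actions = cohort.designs[0].n_actions if cohort.designs else 2
    return (np.concatenate(stim).astype(np.int64),
            np.concatenate(act).astype(np.int64),
            np.concatenate(rew).astype(np.float64),
            np.concatenate(miss).astype(np.int64),
            np.array(ptr, dtype=np.int64), n_stimuli, n_actions)


def _init_state(rng, n_part, K, P, lo, hi, sd_max, free_params):
    theta0 = np.empty((n_part, K))
    for k in range(K):
        # overdispersed but sane starting region (beta away from its far tail)
        frac_hi = 0.5 if free_params[k] == "beta" else 0.7
        theta0[:, k] = lo[k] + (hi[k] - lo[k]) * rng.uniform(0.05, frac_hi, n_part)
    coef0 = np.zeros((K, P))
    coef0[:, 0] = theta0.mean(axis=0)
    if P > 1:
        coef0[:, 1:] = rng.normal(0, 0.05, (K, P - 1)) * (hi - lo)[:, None]
    sigma0 = sd_max * rng.uniform(0.1, 0.4, K)
    return theta0, coef0, sigma0


def _run_fit(model_spec, cohort, X, prior_spec, config, coef_names,
             age_mean=None, age_sd=None) -> PosteriorSamples:
    packed = _pack_cohort(cohort)
    stim, act, rew, miss, ptr, n_stimuli, n_actions = packed
    lo, hi, sd_max, coef_sd = prior_spec.bounds(model_spec)
    n_part, K, P = len(cohort.sessions), model_spec.n_free, X.shape[1]

    theta = np.empty((config.n_chains, config.n_samples, n_part, K))
    coef = np.empty((config.n_chains, config.n_samples, K, P))
    sigma = np.empty((config.n_chains, config.n_samples, K))
    master = np.random.default_rng(config.seed)
    for c in range(config.n_chains):
        chain_seed = int(master.integers(0, 2**31 - 1))
        theta0, coef0, sigma0 = _init_state(
            np.random.default_rng(chain_seed + 1), n_part, K, P, lo, hi, sd_max,
            model_spec.free_params)
        _sampler.run_chain(
            chain_seed, MODEL_CODES[model_spec.name], stim, act, rew, miss, ptr,
            n_stimuli, n_actions, X, lo, hi, coef_sd, sd_max,
            config.warmup_sweeps, config.n_samples, config.thin,
            config.adapt_interval, theta0, coef0, sigma0,
            theta[c], coef[c], sigma[c])
    return PosteriorSamples(
        model=model_spec, theta=theta, coef=coef, sigma=sigma,
        participant_ids=list(cohort.participants["participant"]),
        free_params=model_spec.free_params, coef_names=coef_names,
        age_mean=age_mean, age_sd=age_sd, _packed=packed)


def fit_hierarchical(model_spec: ModelSpec | str, cohort: CohortData,
                     prior_spec: PriorSpec = PriorSpec(),
                     sampler_config: SamplerConfig = SamplerConfig(),
                     ) -> PosteriorSamples:
    """Joint posterior over individual and group parameters (no regression)."""
    model_spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    X = np.ones((len(cohort.sessions), 1))
    return _run_fit(model_spec, cohort, X, prior_spec, sampler_config,
                    coef_names=("intercept",))


def fit_hierarchical_age_regression(model_spec: ModelSpec | str, cohort: CohortData,
                                    age_spec: AgeRegressionSpec = AgeRegressionSpec(),
                                    prior_spec: PriorSpec = PriorSpec(),
                                    sampler_config: SamplerConfig = SamplerConfig(),
                                    ) -> PosteriorSamples:
    """As :func:`fit_hierarchical`, but the group mean of each target parameter
    is intercept + linear*z(age) (+ quadratic*z(age)^2).

    Age is z-scored with the analyzed sample's mean/sd, stored on the result.
    Every free parameter receives regression coefficients (the design matrix
    is shared); callers typically examine only the targets in ``age_spec``.
    """
    model_spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    ages = cohort.participants["age"].to_numpy(float)
    if np.isnan(ages).any():
        raise ValueError("ages required for every participant")
    mu, sd = float(ages.mean()), float(ages.std())
    z = (ages - mu) / (sd if sd > 0 else 1.0)
    cols = [np.ones_like(z), z]
    names = ["intercept", "linear"]
    if age_spec.degree == 2:
        cols.append(z**2)
        names.append("quadratic")
    X = np.column_stack(cols)
    return _run_fit(model_spec, cohort, X, prior_spec, sampler_config,
                    coef_names=tuple(names), age_mean=mu, age_sd=sd)


@dataclass
class Diagnostics:
    rhat: dict
    ess: dict
    max_rhat: float
    min_ess: float
    n_chains: int
    divergences: int
    passed: bool


def diagnostics(posterior: PosteriorSamples, rhat_max: float = 1.05,
                ess_per_chain: float = 25.0) -> Diagnostics:
    """Split-R-hat and ESS for every free parameter (individual and group),
    judged against the convergence criteria."""
    import arviz as az

    if posterior.n_chains < 2:
        raise ValueError("R-hat requires >= 2 chains")
    idata = posterior.to_inference_data()
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {v: float(np.nanmax(rhat_ds[v].values)) for v in rhat_ds.data_vars}
    ess = {v: float(np.nanmin(ess_ds[v].values)) for v in ess_ds.data_vars}
    max_rhat = max(rhat.values())
    min_ess = min(ess.values())
    passed = (max_rhat < rhat_max
              and min_ess > ess_per_chain * posterior.n_chains
              and posterior.divergences == 0)
    return Diagnostics(rhat=rhat, ess=ess, max_rhat=max_rhat, min_ess=min_ess,
                       n_chains=posterior.n_chains,
                       divergences=posterior.divergences, passed=passed)


def credible_interval(posterior: PosteriorSamples, quantity: str,
                      level: float = 0.95) -> dict:
    """Central quantile interval and the excludes-zero decision flag."""
    draws = posterior.draws(quantity)
    lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2])
    return {"low": float(lo), "high": float(hi),
            "mean": float(draws.mean()),
            "excludes_zero": bool(lo > 0 or hi < 0)}


def fit_mle_per_subject(model_spec: ModelSpec | str, trial_data: TrialData,
                        n_restarts: int = 10, beta_max: float = 30.0,
                        seed: int = 0) -> tuple[Params, float]:
    """Bounded maximum-likelihood fit of one session with random restarts."""
    model_spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    rng = np.random.default_rng(seed)
    bounds = model_spec.free_bounds(beta_max)

    def nll(free):
        total, _ = session_loglik(model_spec.expand(free), model_spec, trial_data)
        return -total

    best = None
    n_fail = 0
    for _ in range(n_restarts):
        x0 = np.array([rng.uniform(lo + 0.02 * (hi - lo), lo + 0.8 * (hi - lo))
                       for lo, hi in bounds])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            n_fail += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts failed ({n_fail} non-finite)")
    return model_spec.expand(best.x), -float(best.fun)
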