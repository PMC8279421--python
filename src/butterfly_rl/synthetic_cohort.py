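"""Synthetic cohorts with the statistical structure the analysis assumes.

Generates participants whose RL parameters follow truncated-normal laws whose
means vary with z-scored age (linear + quadratic), with age-correlated puberty
covariates (PDS, salivary testosterone T1), lognormal reaction times whose
median decreases with age, injected missing trials, and a minority of
"off-task" reward-insensitive participants (uniform-random choosers and
perseverators) for exercising the exclusion rules.

Default generative settings place the group-level mean of alpha+ near 0.18
with positive linear and negative quadratic age trends on alpha+ and beta and
a weak negative trend on f — the regime the fitted cohort occupies. Ages
oversample 8-18 roughly 2:1 relative to 18-30. The puberty laws are logistic
in age plus noise: a device for exercising the regression code, not a
scientific model of puberty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rl_models import ModelSpec, Params, get_model, simulate_agent
from .task_env import TaskDesign, TrialData, make_design, with_missing


@dataclass(frozen=True)
class ParamLaw:
    """Truncated normal with an age-polynomial mean: N(b0 + b1 z + b2 z^2, sd) T[lo, hi]."""

    intercept: float
    linear: float = 0.0
    quadratic: float = 0.0
    sd: float = 0.1
    lo: float = 0.0
    hi: float = 1.0

    def mean_at(self, z_age: float) -> float:
        return self.intercept + self.linear * z_age + self.quadratic * z_age**2


@dataclass(frozen=True)
class GroupConfig:
    n_participants: int = 60
    laws: dict = field(default_factory=lambda: dict(DEFAULT_LAWS))
    age_range: tuple = (8.0, 30.0)
    young_fraction: float = 2.0 / 3.0  # mass on 8-18 (oversampled) vs 18-30
    sex_ratio: float = 0.5
    p_off_task: float = 0.0
    missing_rate: float = 0.0
    rt_median_intercept: float = 1.45   # seconds at age 8
    rt_median_slope: float = -0.025     # per year of age
    rt_sigma: float = 0.35              # lognormal shape
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for p in (self.young_fraction, self.sex_ratio, self.p_off_task, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for law in self.laws.values():
            if law.sd < 0:
                raise ValueError("law sd must be >= 0")
            if law.lo >= law.hi:
                raise ValueError("truncation bounds must be ordered")


#: defaults near the fitted scale of the developmental cohort
DEFAULT_LAWS = {
    "alpha_pos": ParamLaw(0.18, 0.06, -0.04, sd=0.08, lo=0.0, hi=1.0),
    "alpha_neg": ParamLaw(0.02, 0.0, 0.0, sd=0.02, lo=0.0, hi=1.0),
    "beta": ParamLaw(6.0, 2.0, -1.0, sd=2.0, lo=0.0, hi=30.0),
    "f": ParamLaw(0.10, -0.02, 0.0, sd=0.05, lo=0.0, hi=1.0),
}


@dataclass
class CohortData:
    """Participant table + one session per participant + the designs used."""

    participants: pd.DataFrame
    sessions: list  # list[TrialData], aligned with participants rows
    designs: list   # list[TaskDesign]
    config: GroupConfig | None = None

    @property
    def n(self) -> int:
        return len(self.sessions)

    def __post_init__(self):
        ids = self.participants["participant"]
        if ids.duplicated().any():
            raise ValueError("participant ids must be unique")
        if len(ids) != len(self.sessions) or len(ids) != len(self.designs):
            raise ValueError("participants, sessions and designs must align")

    def subset(self, keep_mask) -> "CohortData":
        keep = np.asarray(keep_mask, dtype=bool)
        return CohortData(
            participants=self.participants.loc[keep].reset_index(drop=True),
            sessions=[s for s, k in zip(self.sessions, keep) if k],
            designs=[d for d, k in zip(self.designs, keep) if k],
            config=self.config,
        )

    def true_params(self, model_spec: ModelSpec) -> np.ndarray:
        """(n, n_free) matrix of generating parameter values (synthetic cohorts)."""
        cols = [f"true_{p}" for p in model_spec.free_params]
        return self.participants[cols].to_numpy(float)


def _truncnorm_draw(mean, sd, lo, hi, rng) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    # mean far outside bounds with tiny sd: fall back to the nearer bound
    return float(np.clip(mean, lo, hi))


def sample_ages(config: GroupConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.age_range
    split = min(18.0, hi)
    young = rng.random(config.n_participants) < config.young_fraction
    ages = np.where(
        young,
        rng.uniform(lo, split, config.n_participants),
        rng.uniform(split, hi, config.n_participants),
    )
    return ages


def sample_participant_params(config: GroupConfig, age: float, rng: np.random.Generator,
                              z_mean: float = 19.0, z_sd: float = 6.0) -> Params:
    """Draw one participant's full parameter vector from the age-dependent laws."""
    z = (age - z_mean) / z_sd
    vals = {}
    for name, law in config.laws.items():
        vals[name] = _truncnorm_draw(law.mean_at(z), law.sd, law.lo, law.hi, rng)
    return Params(**vals)


def _puberty(age: float, sex: int, rng: np.random.Generator) -> tuple[float, float]:
    # logistic-in-age stand-ins; females (sex=1) shifted ~1 year earlier
    shift = -1.0 if sex == 1 else 0.0
    pds = 1.0 + 3.0 / (1.0 + np.exp(-(age + shift - 12.5) / 1.3)) + rng.normal(0, 0.25)
    pds = float(np.clip(pds, 1.0, 4.0))
    t1 = 1.0 / (1.0 + np.exp(-(age + shift - 13.0) / 1.6)) + rng.normal(0, 0.12)
    return pds, float(t1)


class _PerseveratorPolicy:
    """Off-task archetype: always repeats one fixed choice per stimulus."""

    def __init__(self, n_stimuli: int, n_actions: int, rng: np.random.Generator):
        self.choice = rng.integers(0, n_actions, size=n_stimuli)
        self.n_actions = n_actions

    def act(self, stimulus: int) -> np.ndarray:
        p = np.zeros(self.n_actions)
        p[self.choice[stimulus]] = 1.0
        return p

    def observe(self, *_):
        pass


def generate_cohort(config: GroupConfig, model_spec: ModelSpec | str = "apos0bf",
                    rng: np.random.Generator | None = None,
                    design_kwargs: dict | None = None) -> CohortData:
    """Generate a full synthetic cohort: covariates, parameters, sessions."""
    from .task_env import run_session  # local to avoid cycle at import time

    model_spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    rng = np.random.default_rng(config.seed) if rng is None else rng
    design_kwargs = design_kwargs or {}

    ages = sample_ages(config, rng)
    z_mean, z_sd = float(ages.mean()), float(ages.std() or 1.0)
    rows, sessions, designs = [], [], []
    for j in range(config.n_participants):
        pid = f"sub{j:04d}"
        sex = int(rng.random() < config.sex_ratio)
        pds, t1 = _puberty(ages[j], sex, rng)
        params = sample_participant_params(config, ages[j], rng, z_mean, z_sd)
        params = model_spec.expand([getattr(params, p) for p in model_spec.free_params])
        design = make_design(seed=int(rng.integers(0, 2**31 - 1)), **design_kwargs)
        off_task = int(rng.random() < config.p_off_task)
        if off_task:
            archetype = rng.integers(0, 2)
            if archetype == 0:
                from .task_env import UniformPolicy
                policy = UniformPolicy(design.n_actions)
            else:
                policy = _PerseveratorPolicy(design.n_stimuli, design.n_actions, rng)
            trials = run_session(policy, design, rng, participant_id=pid)
        else:
            trials = simulate_agent(params, model_spec, design, rng, participant_id=pid)
        trials = _attach_rts(trials, ages[j], config, rng)
        if config.missing_rate > 0:
            trials = with_missing(trials, config.missing_rate, rng)
            trials.participant_id = pid
        row = dict(participant=pid, age=ages[j], sex=sex, pds=pds, t1=t1,
                   off_task=off_task)
        row.update({f"true_{k}": getattr(params, k) for k in
                    ("alpha_pos", "alpha_neg", "beta", "f")})
        rows.append(row)
        sessions.append(trials)
        designs.append(design)
    return CohortData(pd.DataFrame(rows), sessions, designs, config=config)


def _attach_rts(trials: TrialData, age: float, config: GroupConfig,
                rng: np.random.Generator) -> TrialData:
    median = max(0.2, config.rt_median_intercept + config.rt_median_slope * (age - 8.0))
    rts = median * np.exp(rng.normal(0.0, config.rt_sigma, trials.n_trials))
    trials.rt = np.minimum(rts, 7.0)
    return trials


def make_recovery_grid(model_spec: ModelSpec | str, grid: dict | None,
                       n_per_cell: int, rng: np.random.Generator,
                       draw_laws: dict | None = None,
                       design_kwargs: dict | None = None) -> CohortData:
    """Cohort with known parameters on an explicit grid (or drawn from laws).

    ``grid`` maps free-parameter names to value lists; the Cartesian product is
    taken and each cell replicated ``n_per_cell`` times. When ``grid`` is None,
    parameters are drawn from ``draw_laws`` (defaulting to the cohort laws).
    """
    model_spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    design_kwargs = design_kwargs or {}
    if grid is not None:
        if not grid or any(len(v) == 0 for v in grid.values()):
            raise ValueError("grid must be non-empty")
        names = list(grid)
        mesh = np.meshgrid(*[np.asarray(grid[n], float) for n in names], indexing="ij")
        cells = np.stack([m.ravel() for m in mesh], axis=1)
        free_rows = np.repeat(cells, n_per_cell, axis=0)
        free_values = []
        for row in free_rows:
            d = {p: 0.0 for p in model_spec.free_params}
            d.update(zip(names, row))
            free_values.append([d[p] for p in model_spec.free_params])
    else:
        laws = draw_laws or {k: v for k, v in DEFAULT_LAWS.items()}
        free_values = []
        for _ in range(n_per_cell):
            vals = []
            for p in model_spec.free_params:
                law = laws[p]
                vals.append(_truncnorm_draw(law.intercept, law.sd, law.lo, law.hi, rng))
            free_values.append(vals)

    rows, sessions, designs = [], [], []
    for j, fv in enumerate(free_values):
        pid = f"grid{j:04d}"
        params = model_spec.expand(fv)
        design = make_design(seed=int(rng.integers(0, 2**31 - 1)), **design_kwargs)
        trials = simulate_agent(params, model_spec, design, rng, participant_id=pid)
        row = dict(participant=pid, age=np.nan, sex=0, pds=np.nan, t1=np.nan, off_task=0)
        row.update({f"true_{k}": getattr(params, k) for k in
                    ("alpha_pos", "alpha_neg", "beta", "f")})
        rows.append(row)
        sessions.append(trials)
        designs.append(design)
    return CohortData(pd.DataFrame(rows), sessions, designs)
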