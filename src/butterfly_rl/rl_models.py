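"""The six reinforcement-learning model variants.

Each model is a (likelihood over choices, generative agent) pair built from the
same four primitives: Q initialization at the uninformative value 0.5, softmax
choice with inverse temperature beta, a delta-rule update whose learning rate
depends on the sign of the reward prediction error (alpha+ for positive RPE,
alpha- otherwise), and per-trial decay of all non-updated Q values toward 0.5
at rate f. Variants fix subsets of (alpha+, alpha-, beta, f):

====== ============================ ==========================
name   free parameters              fixed / tied
====== ============================ ==========================
ab     alpha, beta                  alpha- = alpha+, f = 0
apanb  alpha+, alpha-, beta         f = 0
apos0b alpha+, beta                 alpha- = 0, f = 0
abf    alpha, beta, f               alpha- = alpha+
apanbf alpha+, alpha-, beta, f      (none)
apos0bf alpha+, beta, f             alpha- = 0
====== ============================ ==========================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .task_env import TaskDesign, TrialData

Q_INIT = 0.5

#: canonical order of the full parameter vector
PARAM_FIELDS = ("alpha_pos", "alpha_neg", "beta", "f")


@dataclass(frozen=True)
class Params:
    """One participant's parameter vector (fixed components stored explicitly)."""

    alpha_pos: float
    alpha_neg: float
    beta: float
    f: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.alpha_pos <= 1.0 and 0.0 <= self.alpha_neg <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if not self.beta >= 0.0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.alpha_pos, self.alpha_neg, self.beta, self.f)


@dataclass(frozen=True)
class ModelSpec:
    """Which variant: free parameters, fixed constants, and the tie rule."""

    name: str
    free_params: tuple[str, ...]
    fixed_params: dict
    tie_alphas: bool = False  # single-alpha models: alpha_neg := alpha_pos

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def expand(self, free_values) -> Params:
        """Build a full Params from values of the free parameters (in order)."""
        d = dict(self.fixed_params)
        d.update(zip(self.free_params, free_values))
        if self.tie_alphas:
            d["alpha_neg"] = d["alpha_pos"]
        return Params(**d)

    def check(self, params: Params) -> None:
        """Raise if ``params`` violates this variant's fixed/tied components."""
        for k, v in self.fixed_params.items():
            if getattr(params, k) != v:
                raise ValueError(f"model {self.name} fixes {k}={v}")
        if self.tie_alphas and params.alpha_pos != params.alpha_neg:
            raise ValueError(f"model {self.name} ties alpha_neg to alpha_pos")

    def free_bounds(self, beta_max: float = 30.0) -> list[tuple[float, float]]:
        return [(0.0, beta_max) if p == "beta" else (0.0, 1.0) for p in self.free_params]


MODELS: dict[str, ModelSpec] = {
    "ab": ModelSpec("ab", ("alpha_pos", "beta"), {"f": 0.0}, tie_alphas=True),
    "apanb": ModelSpec("apanb", ("alpha_pos", "alpha_neg", "beta"), {"f": 0.0}),
    "apos0b": ModelSpec("apos0b", ("alpha_pos", "beta"), {"alpha_neg": 0.0, "f": 0.0}),
    "abf": ModelSpec("abf", ("alpha_pos", "beta", "f"), {}, tie_alphas=True),
    "apanbf": ModelSpec("apanbf", ("alpha_pos", "alpha_neg", "beta", "f"), {}),
    "apos0bf": ModelSpec("apos0bf", ("alpha_pos", "beta", "f"), {"alpha_neg": 0.0}),
}

#: unicode names as printed in the literature, accepted as aliases
ALIASES = {
    "αβ": "ab",
    "α⁺α⁻β": "apanb",
    "α⁺0β": "apos0b",
    "αβf": "abf",
    "α⁺α⁻βf": "apanbf",
    "α⁺0βf": "apos0bf",
}


def get_model(name: str) -> ModelSpec:
    key = ALIASES.get(name, name)
    if key not in MODELS:
        raise KeyError(f"unknown model {name!r}; known: {sorted(MODELS)}")
    return MODELS[key]


def init_q(n_stimuli: int, n_actions: int) -> np.ndarray:
    """Q table with every entry at the uninformative value 0.5."""
    if n_stimuli < 1 or n_actions < 1:
        raise ValueError("counts must be >= 1")
    return np.full((n_stimuli, n_actions), Q_INIT)


def choice_prob(q_table: np.ndarray, stimulus: int, beta: float) -> np.ndarray:
    """Softmax action probabilities for one stimulus (max-subtracted for safety)."""
    row = np.asarray(q_table[stimulus], dtype=float)
    if not (np.isfinite(row).all() and np.isfinite(beta)) or beta < 0:
        raise ValueError("Q values and beta must be finite, beta >= 0")
    z = beta * (row - row.max())
    e = np.exp(z)
    return e / e.sum()


def update(q_table: np.ndarray, stimulus: int, action: int, reward: int,
           params: Params) -> np.ndarray:
    """Delta-rule update of the chosen pair; learning rate picked by RPE sign.

    A zero RPE routes to alpha- (the update is zero either way).
    """
    if reward not in (0, 1):
        raise ValueError("reward must be 0 or 1")
    q = q_table.copy()
    rpe = reward - q[stimulus, action]
    alpha = params.alpha_pos if rpe > 0 else params.alpha_neg
    q[stimulus, action] += alpha * rpe
    return q


def apply_forgetting(q_table: np.ndarray, stimulus: int, action: int, f: float) -> np.ndarray:
    """Decay every pair except (stimulus, action) toward 0.5 at rate f."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    q = (1.0 - f) * q_table + f * Q_INIT
    q[stimulus, action] = q_table[stimulus, action]
    return q


def session_loglik(params: Params, model_spec: ModelSpec, trial_data: TrialData,
                   n_stimuli: int | None = None, n_actions: int | None = None):
    """Choice log-likelihood of one session under a model variant.

    Returns ``(total, pointwise)`` where ``pointwise`` has one entry per
    non-missing trial in trial order. The probability of each choice is
    evaluated on the Q state *before* that trial's update; missing trials
    contribute no likelihood term and no update, but forgetting still applies.
    """
    model_spec.check(params)
    trial_data.validate()
    if n_stimuli is None:
        n_stimuli = int(trial_data.stimulus.max()) + 1
    if n_actions is None:
        n_actions = max(int(trial_data.action.max()) + 1, 2)
    ap, an, beta, f = params.as_tuple()
    pointwise = np.empty(trial_data.n_trials)
    total, k = _kernels.session_loglik(
        ap, an, beta, f,
        trial_data.stimulus.astype(np.int64),
        trial_data.action.astype(np.int64),
        trial_data.reward.astype(np.float64),
        trial_data.missing.astype(np.int64),
        n_stimuli, n_actions, pointwise,
    )
    return total, pointwise[:k].copy()


class RLAgentPolicy:
    """Stateful agent usable with :func:`butterfly_rl.task_env.run_session`."""

    def __init__(self, params: Params, model_spec: ModelSpec,
                 n_stimuli: int, n_actions: int):
        model_spec.check(params)
        self.params = params
        self.q = init_q(n_stimuli, n_actions)

    def act(self, stimulus: int) -> np.ndarray:
        return choice_prob(self.q, stimulus, self.params.beta)

    def observe(self, stimulus: int, action: int, reward: int) -> None:
        self.q = update(self.q, stimulus, action, reward, self.params)
        if self.params.f > 0:
            self.q = apply_forgetting(self.q, stimulus, action, self.params.f)


def simulate_agent(params: Params, model_spec: ModelSpec, design: TaskDesign,
                   rng_or_seed, participant_id: str = "sim") -> TrialData:
    """Simulate a full session (fast path; seeded-deterministic)."""
    model_spec.check(params)
    if isinstance(rng_or_seed, np.random.Generator):
        seed = int(rng_or_seed.integers(0, 2**31 - 1))
    else:
        seed = int(rng_or_seed)
    n = design.n_trials
    actions = np.empty(n, dtype=np.int64)
    rewards = np.empty(n, dtype=np.int64)
    ap, an, beta, f = params.as_tuple()
    _kernels.seed(seed)
    _kernels.simulate_session(
        ap, an, beta, f,
        design.stimulus_sequence.astype(np.int64),
        design.correct_action.astype(np.int64),
        design.reward_draw.astype(np.int64),
        design.n_stimuli, design.n_actions, actions, rewards,
    )
    return TrialData(
        participant_id=participant_id,
        stimulus=design.stimulus_sequence.copy(),
        action=actions,
        reward=rewards,
        rt=np.full(n, np.nan),
        missing=np.zeros(n, dtype=np.int64),
        correct_action=design.correct_action.copy(),
    )
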