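"""Butterfly-task environment: session designs, feedback adjudication, agent harness.

The task is a contextual two-armed bandit. Each of four stimuli ("butterflies")
has one fixed preferred action ("flower"). Choosing the preferred action yields
positive feedback with probability ``reward_prob`` (default 0.8); on the
remaining trials the *other* action is the rewarding one. The reward schedule is
therefore a single Bernoulli draw per trial indicating which action pays out,
not independent draws per action.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1
RESPONSE_WINDOW_S = 7.0


@dataclass(frozen=True)
class TaskDesign:
    """A pre-randomized session: stimulus order, correct-action map, reward draws.

    ``reward_draw[t] == 1`` means the designated-correct action is the rewarded
    one on trial ``t``; ``0`` means the other action is.
    """

    n_stimuli: int
    n_actions: int
    trials_per_stimulus: int
    stimulus_sequence: np.ndarray
    correct_action: np.ndarray  # indexed by stimulus id
    reward_draw: np.ndarray
    reward_prob: float = 0.8
    seed: int = 0
    response_window_s: float = RESPONSE_WINDOW_S

    @property
    def n_trials(self) -> int:
        return self.n_stimuli * self.trials_per_stimulus

    def __post_init__(self):
        counts = np.bincount(self.stimulus_sequence, minlength=self.n_stimuli)
        if not np.all(counts == self.trials_per_stimulus):
            raise ValueError("each stimulus must appear exactly trials_per_stimulus times")
        if len(self.reward_draw) != self.n_trials:
            raise ValueError("reward_draw length must equal the number of trials")


@dataclass
class TrialData:
    """One participant's session, trial by trial.

    Missing trials carry ``action == MISSING`` (and reward/rt are meaningless
    there); ``missing`` is the authoritative flag.
    """

    participant_id: str
    stimulus: np.ndarray
    action: np.ndarray
    reward: np.ndarray
    rt: np.ndarray
    missing: np.ndarray
    correct_action: np.ndarray = field(default=None)  # per stimulus id

    @property
    def n_trials(self) -> int:
        return len(self.stimulus)

    @property
    def correct(self) -> np.ndarray:
        """Per-trial correctness (MISSING on missed trials)."""
        out = np.full(self.n_trials, MISSING, dtype=np.int64)
        ok = ~self.missing.astype(bool)
        out[ok] = (
            self.action[ok] == self.correct_action[self.stimulus[ok]]
        ).astype(np.int64)
        return out

    def validate(self) -> None:
        n = self.n_trials
        for name in ("action", "reward", "rt", "missing"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        ok = ~self.missing.astype(bool)
        if not np.isin(self.reward[ok], (0, 1)).all():
            raise ValueError("reward must be 0/1 on non-missing trials")


def make_design(
    n_stimuli: int = 4,
    n_actions: int = 2,
    trials_per_stimulus: int = 30,
    reward_prob: float = 0.8,
    seed: int = 0,
    max_run: int = 4,
    exact_counts: bool = False,
) -> TaskDesign:
    """Generate a pre-randomized session design.

    The stimulus order is a seeded random interleaving with at most ``max_run``
    consecutive repeats of one stimulus. ``exact_counts=True`` counterbalances
    reward draws to exactly ``round(reward_prob * trials_per_stimulus)`` rewarded
    correct-choice trials per stimulus instead of free Bernoulli draws.
    """
    if n_stimuli < 1 or n_actions < 1 or trials_per_stimulus < 1:
        raise ValueError("counts must be >= 1")
    if not 0.5 < reward_prob <= 1.0:
        raise ValueError("reward_prob must lie in (0.5, 1]")
    rng = np.random.default_rng(seed)

    base = np.repeat(np.arange(n_stimuli), trials_per_stimulus)
    seq = _permute_capped(base, rng, max_run) if n_stimuli > 1 else base
    correct = rng.integers(0, n_actions, size=n_stimuli)

    if exact_counts:
        draw = np.empty(len(seq), dtype=np.int64)
        n_hi = int(round(reward_prob * trials_per_stimulus))
        for s in range(n_stimuli):
            idx = np.flatnonzero(seq == s)
            cell = np.zeros(trials_per_stimulus, dtype=np.int64)
            cell[:n_hi] = 1
            draw[idx] = rng.permutation(cell)
    else:
        draw = (rng.random(len(seq)) < reward_prob).astype(np.int64)

    return TaskDesign(
        n_stimuli=n_stimuli,
        n_actions=n_actions,
        trials_per_stimulus=trials_per_stimulus,
        stimulus_sequence=seq,
        correct_action=correct,
        reward_draw=draw,
        reward_prob=reward_prob,
        seed=seed,
    )


def _permute_capped(base: np.ndarray, rng: np.random.Generator, max_run: int) -> np.ndarray:
    """Seeded permutation with <= max_run consecutive repeats (resample on violation)."""
    for _ in range(1000):
        seq = rng.permutation(base)
        if _longest_run(seq) <= max_run:
            return seq
    raise RuntimeError("could not satisfy the run-length cap; raise max_run")


def _longest_run(seq: np.ndarray) -> int:
    best = run = 1
    for a, b in zip(seq[:-1], seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def adjudicate(design: TaskDesign, trial_index: int, action: int) -> int:
    """Return the 0/1 reward for taking ``action`` on trial ``trial_index``."""
    if not 0 <= action < design.n_actions:
        raise ValueError(f"unknown action id {action}")
    stim = design.stimulus_sequence[trial_index]
    is_correct = action == design.correct_action[stim]
    return int(is_correct == bool(design.reward_draw[trial_index]))


def run_session(agent_policy, design: TaskDesign, rng: np.random.Generator,
                participant_id: str = "sim") -> TrialData:
    """Run a stateful agent through a session.

    ``agent_policy`` exposes ``act(stimulus) -> probability vector`` and
    ``observe(stimulus, action, reward)``. Choices are sampled with ``rng``;
    rewards come from :func:`adjudicate`. Never produces missing trials.
    """
    n = design.n_trials
    actions = np.empty(n, dtype=np.int64)
    rewards = np.empty(n, dtype=np.int64)
    for t in range(n):
        stim = int(design.stimulus_sequence[t])
        p = np.asarray(agent_policy.act(stim), dtype=float)
        if p.shape != (design.n_actions,) or not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError("policy must return a normalized probability vector")
        a = int(rng.choice(design.n_actions, p=p))
        r = adjudicate(design, t, a)
        agent_policy.observe(stim, a, r)
        actions[t] = a
        rewards[t] = r
    return TrialData(
        participant_id=participant_id,
        stimulus=design.stimulus_sequence.copy(),
        action=actions,
        reward=rewards,
        rt=np.full(n, np.nan),
        missing=np.zeros(n, dtype=np.int64),
        correct_action=design.correct_action.copy(),
    )


class OraclePolicy:
    """Always chooses each stimulus's preferred action (or always avoids it)."""

    def __init__(self, design: TaskDesign, invert: bool = False):
        self.design = design
        self.invert = invert

    def act(self, stimulus: int) -> np.ndarray:
        p = np.zeros(self.design.n_actions)
        best = self.design.correct_action[stimulus]
        if self.invert:
            p[np.arange(self.design.n_actions) != best] = 1.0 / (self.design.n_actions - 1)
        else:
            p[best] = 1.0
        return p

    def observe(self, stimulus, action, reward):
        pass


class UniformPolicy:
    """Reward-insensitive uniform-random chooser."""

    def __init__(self, n_actions: int):
        self.n_actions = n_actions

    def act(self, stimulus: int) -> np.ndarray:
        return np.full(self.n_actions, 1.0 / self.n_actions)

    def observe(self, stimulus, action, reward):
        pass


def with_missing(trials: TrialData, missing_rate: float, rng: np.random.Generator) -> TrialData:
    """Return a copy with trials knocked out at ``missing_rate`` (no response recorded)."""
    miss = (rng.random(trials.n_trials) < missing_rate).astype(np.int64)
    action = trials.action.copy()
    reward = trials.reward.copy()
    rt = trials.rt.copy()
    action[miss == 1] = MISSING
    reward[miss == 1] = MISSING
    rt[miss == 1] = np.nan
    return replace(trials, action=action, reward=reward, rt=rt, missing=miss)
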