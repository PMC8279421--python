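import numpy as np
import pytest

from butterfly_rl.rl_models import MODELS, Params, get_model, simulate_agent
from butterfly_rl.synthetic_cohort import GroupConfig, generate_cohort
from butterfly_rl.task_env import make_design


@pytest.fixture(scope="session")
def default_design():
    return make_design(seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """12 clean on-task participants from the winning-model generator."""
    return generate_cohort(GroupConfig(n_participants=12, seed=5), "apos0bf")


def random_session(rng, model_name=None, params=None):
    """One simulated session with random-but-sane parameters."""
    model = get_model(model_name or rng.choice(list(MODELS)))
    if params is None:
        params = model.expand([
            rng.uniform(0.05, 0.95) if p != "beta" else rng.uniform(0.5, 12.0)
            for p in model.free_params
        ])
    design = make_design(seed=int(rng.integers(0, 2**31 - 1)))
    td = simulate_agent(params, model, design, int(rng.integers(0, 2**31 - 1)))
    return model, params, design, td
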