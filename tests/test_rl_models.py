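import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from butterfly_rl.rl_models import (MODELS, Params, apply_forgetting,
                                    choice_prob, get_model, init_q,
                                    session_loglik, simulate_agent, update)
from butterfly_rl.task_env import make_design

from .conftest import random_session
from .oracles import naive_session_loglik


class TestPrimitives:
    def test_init_q_uniform_at_half(self):
        q = init_q(4, 2)
        assert q.shape == (4, 2)
        assert (q == 0.5).all()
        assert init_q(1, 1).item() == 0.5

    def test_init_q_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            init_q(0, 2)

    def test_choice_prob_symmetry_and_beta_zero(self):
        q = init_q(4, 2)
        assert np.allclose(choice_prob(q, 0, 5.0), [0.5, 0.5])
        q[1] = [0.9, 0.1]
        assert np.allclose(choice_prob(q, 1, 0.0), [0.5, 0.5])

    def test_choice_prob_hand_arithmetic(self):
        # Q=(1,0), beta=ln 9 -> e^beta/(e^beta+1) = 0.9
        q = init_q(1, 2)
        q[0] = [1.0, 0.0]
        p = choice_prob(q, 0, math.log(9))
        assert np.allclose(p, [0.9, 0.1], atol=1e-12)

    def test_choice_prob_shift_invariance(self):
        q = init_q(1, 2)
        q[0] = [0.3, 0.8]
        p1 = choice_prob(q, 0, 4.0)
        q[0] += 17.5
        p2 = choice_prob(q, 0, 4.0)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_update_delta_rule_arithmetic(self):
        q = init_q(1, 2)
        p = Params(0.2, 0.1, 1.0)
        q2 = update(q, 0, 0, 1, p)
        assert q2[0, 0] == pytest.approx(0.6)
        assert q2[0, 1] == 0.5  # untouched

    def test_one_shot_learning_at_alpha_one(self):
        q = init_q(1, 2)
        q[0, 0] = 0.123
        q2 = update(q, 0, 0, 1, Params(1.0, 1.0, 1.0))
        assert q2[0, 0] == 1.0

    def test_zero_negative_learning_rate_ignores_losses(self):
        q = init_q(1, 2)
        q2 = update(q, 0, 0, 0, Params(0.5, 0.0, 1.0))
        assert q2[0, 0] == 0.5

    def test_update_rejects_non_binary_reward(self):
        with pytest.raises(ValueError):
            update(init_q(1, 2), 0, 0, 2, Params(0.5, 0.5, 1.0))

    def test_forgetting_decay_and_limits(self):
        q = init_q(2, 2)
        q[:] = 0.9
        q2 = apply_forgetting(q, 0, 0, 0.1)
        assert q2[0, 0] == 0.9          # current pair untouched
        assert q2[1, 1] == pytest.approx(0.86)  # 0.9*0.9 + 0.1*0.5
        assert (apply_forgetting(q, 0, 0, 0.0) == q).all()
        q3 = apply_forgetting(q, 0, 0, 1.0)
        assert q3[0, 0] == 0.9 and (np.delete(q3.ravel(), 0) == 0.5).all()


class TestSessionLoglik:
    def test_beta_zero_gives_uniform_choice_likelihood(self, default_design):
        model = get_model("ab")
        params = model.expand([0.3, 0.0])
        td = simulate_agent(params, model, default_design, 1)
        total, pw = session_loglik(params, model, td)
        assert total == pytest.approx(120 * math.log(0.5))
        assert len(pw) == 120

    def test_two_trial_hand_worked_case(self):
        from butterfly_rl.task_env import TrialData

        td = TrialData("h", stimulus=np.array([0, 0]), action=np.array([0, 0]),
                       reward=np.array([1, 1]), rt=np.full(2, np.nan),
                       missing=np.zeros(2, dtype=np.int64),
                       correct_action=np.array([0]))
        model = get_model("apos0b")
        params = model.expand([0.5, 2.0])
        total, pw = session_loglik(params, model, td, n_stimuli=1, n_actions=2)
        expected_t2 = math.log(math.exp(1.5) / (math.exp(1.5) + math.exp(1.0)))
        assert pw[0] == pytest.approx(math.log(0.5), abs=1e-12)
        assert pw[1] == pytest.approx(expected_t2, abs=1e-12)
        assert total == pytest.approx(math.log(0.5) + expected_t2, abs=1e-12)

    @pytest.mark.parametrize("model_name", sorted(MODELS))
    def test_matches_naive_loop_oracle(self, model_name):
        rng = np.random.default_rng(hash(model_name) % 2**31)
        for _ in range(12):
            model, params, design, td = random_session(rng, model_name)
            total, pw = session_loglik(params, model, td)
            ref_total, ref_pw = naive_session_loglik(
                params.alpha_pos, params.alpha_neg, params.beta, params.f,
                td, design.n_stimuli, design.n_actions)
            assert total == pytest.approx(ref_total, abs=1e-10)
            np.testing.assert_allclose(pw, ref_pw, atol=1e-10)

    def test_missing_trials_skip_likelihood_but_forget(self):
        rng = np.random.default_rng(11)
        model, params, design, td = random_session(rng, "apos0bf")
        td.missing[10:20] = 1
        total, pw = session_loglik(params, model, td)
        assert len(pw) == 110
        ref_total, _ = naive_session_loglik(
            params.alpha_pos, params.alpha_neg, params.beta, params.f,
            td, design.n_stimuli, design.n_actions)
        assert total == pytest.approx(ref_total, abs=1e-10)

    def test_nesting_equalities_exact(self):
        rng = np.random.default_rng(5)
        _, _, design, td = random_session(rng, "apanbf")
        cases = [
            # (restricted model, free values) == (nesting model, free values)
            (("ab", [0.3, 4.0]), ("apanb", [0.3, 0.3, 4.0])),
            (("apos0b", [0.3, 4.0]), ("apanb", [0.3, 0.0, 4.0])),
            (("apanb", [0.3, 0.2, 4.0]), ("apanbf", [0.3, 0.2, 4.0, 0.0])),
            (("apos0bf", [0.3, 4.0, 0.1]), ("apanbf", [0.3, 0.0, 4.0, 0.1])),
            (("abf", [0.3, 4.0, 0.1]), ("apanbf", [0.3, 0.3, 4.0, 0.1])),
        ]
        for (m1, v1), (m2, v2) in cases:
            s1, _ = session_loglik(get_model(m1).expand(v1), get_model(m1), td)
            s2, _ = session_loglik(get_model(m2).expand(v2), get_model(m2), td)
            assert s1 == s2, (m1, m2)

    def test_model_constraint_violation_rejected(self):
        rng = np.random.default_rng(6)
        _, _, _, td = random_session(rng, "ab")
        bad = Params(alpha_pos=0.3, alpha_neg=0.1, beta=2.0, f=0.0)
        with pytest.raises(ValueError):
            session_loglik(bad, get_model("ab"), td)


class TestSimulateAgent:
    def test_seeded_determinism(self, default_design):
        model = get_model("apos0bf")
        p = model.expand([0.3, 8.0, 0.05])
        a = simulate_agent(p, model, default_design, 123)
        b = simulate_agent(p, model, default_design, 123)
        assert (a.action == b.action).all() and (a.reward == b.reward).all()

    def test_greedy_learner_beats_chance(self, default_design):
        model = get_model("apos0b")
        p = model.expand([0.7, 20.0])
        accs = [simulate_agent(p, model, make_design(seed=s), s).correct.mean()
                for s in range(40)]
        assert np.mean(accs) > 0.65

    def test_learning_curve_rises_across_blocks(self):
        model = get_model("apos0bf")
        p = model.expand([0.25, 7.0, 0.05])
        curves = []
        for s in range(60):
            td = simulate_agent(p, model, make_design(seed=s), s + 1000)
            curves.append(td.correct.reshape(4, 30).mean(axis=1))
        mean = np.mean(curves, axis=0)
        assert mean[3] > mean[0] + 0.05

    def test_data_generating_params_beat_perturbed_params(self):
        model = get_model("apos0b")
        p_true = model.expand([0.3, 6.0])
        p_pert = model.expand([0.9, 1.0])
        ll_true = ll_pert = 0.0
        for s in range(30):
            td = simulate_agent(p_true, model, make_design(seed=s), s)
            ll_true += session_loglik(p_true, model, td)[0]
            ll_pert += session_loglik(p_pert, model, td)[0]
        assert ll_true > ll_pert


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    alpha_pos=st.floats(0, 1), alpha_neg=st.floats(0, 1),
    beta=st.floats(0, 30), f=st.floats(0, 1),
    seed=st.integers(0, 10_000),
)
def test_q_values_stay_bounded(alpha_pos, alpha_neg, beta, f, seed):
    """With 0/1 rewards and 0.5 init, Q stays in [0,1] for any valid params."""
    model = get_model("apanbf")
    params = Params(alpha_pos, alpha_neg, beta, f)
    design = make_design(n_stimuli=2, trials_per_stimulus=10, seed=seed)
    td = simulate_agent(params, model, design, seed)
    q = init_q(2, 2)
    for t in range(td.n_trials):
        s, a, r = int(td.stimulus[t]), int(td.action[t]), int(td.reward[t])
        q = update(q, s, a, r, params)
        q = apply_forgetting(q, s, a, f)
        assert (q >= 0).all() and (q <= 1).all()
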