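import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from butterfly_rl import behavior
from butterfly_rl.behavior import (ExclusionThresholds, apply_exclusions,
                                   bin_by_age, compute_regressors,
                                   fit_linear_quadratic, fit_mixed_logistic,
                                   summarize, two_line_regression)
from butterfly_rl.synthetic_cohort import CohortData, GroupConfig, generate_cohort
from butterfly_rl.task_env import MISSING, TrialData, make_design

from .conftest import random_session
from .oracles import naive_regressors


def make_session(stimuli, actions, rewards, correct_action, missing=None, pid="t"):
    n = len(stimuli)
    return TrialData(
        participant_id=pid,
        stimulus=np.asarray(stimuli, dtype=np.int64),
        action=np.asarray(actions, dtype=np.int64),
        reward=np.asarray(rewards, dtype=np.int64),
        rt=np.full(n, 0.8),
        missing=np.asarray(missing if missing is not None else np.zeros(n),
                           dtype=np.int64),
        correct_action=np.asarray(correct_action, dtype=np.int64),
    )


class TestSummarize:
    def test_all_correct_session_clamps_log_odds(self):
        td = make_session([0, 1] * 60, [0, 1] * 60, [1, 1] * 60, [0, 1])
        s = summarize(td)
        assert (s.block_accuracy == 1.0).all()
        assert s.p_correct == 1.0
        assert np.isfinite(s.log_odds)
        assert s.log_odds == pytest.approx(np.log(120.5 / 0.5))

    def test_alternating_accuracy_gives_zero_log_odds(self):
        td = make_session([0] * 8, [0, 1] * 4, [1, 0] * 4, [0])
        s = summarize(td)
        assert s.p_correct == 0.5
        assert s.log_odds == 0.0

    def test_hand_counted_stay_switch_after_win(self):
        # stim 0 on every trial; wins on trials 0,2,4; choices 0,0,1,1,0,...
        td = make_session([0] * 6, [0, 0, 1, 1, 0, 0], [1, 1, 1, 0, 1, 1], [0])
        s = summarize(td)
        # transitions after rewarded encounters: t0->t1 stay, t1->t2 switch,
        # t2->t3 stay, t4->t5 stay (t3 not rewarded) => 3 stays, 1 switch
        assert s.stay_after_win == pytest.approx(3 / 4)
        assert s.switch_after_win == pytest.approx(1 / 4)

    def test_all_missing_session_raises(self):
        td = make_session([0, 1], [MISSING, MISSING], [MISSING, MISSING],
                          [0, 1], missing=[1, 1])
        with pytest.raises(ValueError):
            summarize(td)


class TestExclusions:
    def _cohort_of(self, sessions):
        participants = pd.DataFrame({
            "participant": [td.participant_id for td in sessions],
            "age": 15.0, "sex": 0, "pds": 2.0, "t1": 0.3, "off_task": 0,
        })
        designs = [make_design(seed=i) for i in range(len(sessions))]
        return CohortData(participants, sessions, designs)

    def test_switch_after_win_participant_excluded(self):
        # pathological switcher: always changes flower after a win
        rng = np.random.default_rng(0)
        d = make_design(seed=0)
        acts = np.zeros(120, dtype=np.int64)
        rews = np.zeros(120, dtype=np.int64)
        last = {}
        from butterfly_rl.task_env import adjudicate
        for t in range(120):
            s = int(d.stimulus_sequence[t])
            prev, prev_r = last.get(s, (0, 0))
            a = 1 - prev if prev_r else prev
            r = adjudicate(d, t, a)
            acts[t], rews[t] = a, r
            last[s] = (a, r)
        td = TrialData("switcher", d.stimulus_sequence, acts, rews,
                       np.full(120, 0.6), np.zeros(120, dtype=np.int64),
                       d.correct_action)
        _, report = apply_exclusions(self._cohort_of([td, _ideal(1)]))
        row = report[report["participant"] == "switcher"].iloc[0]
        assert row["excluded"] and "switch_gt_stay" in row["reason"]

    def test_ideal_learner_kept(self):
        kept, report = apply_exclusions(self._cohort_of([_ideal(0), _ideal(1)]))
        assert not report["excluded"].any()

    def test_near_complete_missingness_excluded(self):
        td = _ideal(0)
        td.missing[:102] = 1
        td.action[:102] = MISSING
        td.reward[:102] = MISSING
        _, report = apply_exclusions(self._cohort_of([td, _ideal(1)]))
        assert report.iloc[0]["excluded"]
        assert "missing" in report.iloc[0]["reason"]

    def test_off_task_archetypes_excluded_in_expectation(self):
        cohort = generate_cohort(GroupConfig(n_participants=60, seed=9,
                                             p_off_task=1.0), "apos0bf")
        _, report = apply_exclusions(cohort)
        # conjunctive rules are probabilistic traps: random choosers trip the
        # switch rule ~half the time, perseverators the below-chance+flag rule
        assert report["excluded"].mean() > 0.3

    def test_tightening_thresholds_never_unexcludes(self):
        cohort = generate_cohort(GroupConfig(n_participants=30, seed=10,
                                             p_off_task=0.3, missing_rate=0.1),
                                 "apos0bf")
        loose = ExclusionThresholds()
        tight = ExclusionThresholds(same_choice_prop=0.7, change_prop=0.7,
                                    longest_run=20, missing_prop=0.2)
        _, rep_loose = apply_exclusions(cohort, loose)
        _, rep_tight = apply_exclusions(cohort, tight)
        assert (rep_tight["excluded"] | ~rep_loose["excluded"]).all()


def _ideal(seed):
    d = make_design(seed=seed)
    acts = d.correct_action[d.stimulus_sequence]
    rews = np.where(d.reward_draw == 1, 1, 0)
    return TrialData(f"ideal{seed}", d.stimulus_sequence.copy(), acts.copy(),
                     rews.astype(np.int64), np.full(120, 0.5),
                     np.zeros(120, dtype=np.int64), d.correct_action.copy())


class TestRegressors:
    def test_hand_counted_example(self):
        # A win, B lose, A ... : at the third trial r(A)=1, d(A)=1
        td = make_session([0, 1, 0], [0, 0, 0], [1, 0, 0], [0, 1])
        df = compute_regressors(td)
        third = df[df["trial"] == 2].iloc[0]
        assert third["r"] == 1 and third["d"] == 1 and third["included"]

    def test_first_encounters_have_no_history(self):
        td = make_session([0, 1, 2, 3], [0] * 4, [1] * 4, [0, 0, 0, 0])
        df = compute_regressors(td)
        assert (df["r"] == 0).all()
        assert (~df["included"]).all()

    def test_all_lose_session_has_no_defined_delay(self):
        td = make_session([0, 1] * 10, [0] * 20, [0] * 20, [0, 0])
        df = compute_regressors(td)
        assert (df["r"] == 0).all() and (~df["included"]).all()

    def test_matches_quadratic_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            _, _, _, td = random_session(rng, "apos0bf")
            td.missing[rng.integers(0, 120, 10)] = 1
            df = compute_regressors(td)
            ref = naive_regressors(td)
            assert len(df) == len(ref)
            for (_, row), (t, r, d) in zip(df.iterrows(), ref):
                assert row["trial"] == t and row["r"] == r
                if d is None:
                    assert not row["included"]
                else:
                    assert row["d"] == d

    def test_z_scores_standardized_over_included_rows(self):
        rng = np.random.default_rng(4)
        _, _, _, td = random_session(rng, "apos0bf")
        df = compute_regressors(td)
        inc = df[df["included"]]
        assert abs(inc["z_r"].mean()) < 1e-10
        assert inc["z_r"].std(ddof=0) == pytest.approx(1.0)


class TestMixedLogistic:
    @staticmethod
    def _simulate_tables(rng, n_sub, beta, sd, n_trial=96):
        tables = {}
        for j in range(n_sub):
            b = rng.normal(0, sd)
            zr = rng.normal(size=n_trial)
            zd = rng.normal(size=n_trial)
            eta = (beta[0] + b[0]) + (beta[1] + b[1]) * zr + (beta[2] + b[2]) * zd
            y = (rng.random(n_trial) < 1 / (1 + np.exp(-eta))).astype(int)
            tables[f"s{j}"] = pd.DataFrame(dict(
                trial=np.arange(n_trial), stimulus=0, r=zr, d=zd,
                correct=y, included=True, z_r=zr, z_d=zd))
        return tables

    def test_fixed_effects_recovered_within_ci(self):
        rng = np.random.default_rng(0)
        beta = np.array([0.3, 0.8, -0.17])
        tables = self._simulate_tables(rng, 150, beta, np.array([0.4, 0.3, 0.1]))
        fit = fit_mixed_logistic(tables, zscore_pooled=False)
        for name, true in zip(("intercept", "r", "d"), beta):
            est, se = fit.fixed_effects[name], fit.se[name]
            assert abs(est - true) < 3 * se, name
        assert fit.p["r"] < 1e-4 and fit.p["d"] < 1e-4

    def test_null_effects_not_detected(self):
        rng = np.random.default_rng(1)
        tables = self._simulate_tables(rng, 80, np.array([0.2, 0.0, 0.0]),
                                       np.array([0.3, 0.05, 0.05]))
        fit = fit_mixed_logistic(tables, zscore_pooled=False)
        assert abs(fit.fixed_effects["r"]) < 3 * fit.se["r"]
        assert abs(fit.fixed_effects["d"]) < 3 * fit.se["d"]

    def test_random_effect_ordering_tracks_true_slopes(self):
        rng = np.random.default_rng(2)
        beta = np.array([0.2, 0.6, -0.2])
        sd = np.array([0.3, 0.4, 0.2])
        tables = {}
        true_slopes = {}
        for j in range(60):
            b = rng.normal(0, sd)
            true_slopes[f"s{j}"] = beta[1] + b[1]
            zr = rng.normal(size=96)
            zd = rng.normal(size=96)
            eta = (beta[0] + b[0]) + (beta[1] + b[1]) * zr + (beta[2] + b[2]) * zd
            y = (rng.random(96) < 1 / (1 + np.exp(-eta))).astype(int)
            tables[f"s{j}"] = pd.DataFrame(dict(
                trial=np.arange(96), stimulus=0, r=zr, d=zd, correct=y,
                included=True, z_r=zr, z_d=zd))
        fit = fit_mixed_logistic(tables, zscore_pooled=False)
        est = fit.random_effects.set_index("participant")["effect_r"]
        truth = pd.Series(true_slopes)
        assert truth.corr(est.loc[truth.index]) > 0.5

    def test_agrees_with_lme4_reference(self, tmp_path):
        """Cross-check fixed effects against glmer (Laplace) on one dataset."""
        rng = np.random.default_rng(7)
        tables = self._simulate_tables(rng, 40, np.array([0.3, 0.7, -0.2]),
                                       np.array([0.4, 0.3, 0.15]))
        fit = fit_mixed_logistic(tables, zscore_pooled=False)
        rows = []
        for pid, df in tables.items():
            df = df.assign(participant=pid)
            rows.append(df)
        data = pd.concat(rows)
        csv = tmp_path / "glmm.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(correct ~ z_r + z_d + (1 + z_r + z_d | participant),
                       data = d, family = binomial)
            cat(fixef(m), sep = "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=600)
        assert out.returncode == 0, out.stderr
        ref = [float(v) for v in out.stdout.strip().splitlines()[-3:]]
        for name, r in zip(("intercept", "r", "d"), ref):
            assert fit.fixed_effects[name] == pytest.approx(r, abs=0.05), (name, ref)


class TestRegressions:
    def test_exact_line_has_no_quadratic_term(self):
        x = np.linspace(0, 10, 40)
        res = fit_linear_quadratic(x, 2 * x + 1)
        assert res.linear["x"]["coef"] == pytest.approx(2.0)
        assert res.linear["intercept"]["coef"] == pytest.approx(1.0)
        assert abs(res.quadratic["x2"]["coef"]) < 1e-8
        assert not res.quadratic_improves

    def test_exact_parabola_recovered(self):
        x = np.linspace(-3, 3, 30)
        res = fit_linear_quadratic(x, 1.5 * x**2 - 0.5 * x + 2)
        assert res.quadratic["x2"]["coef"] == pytest.approx(1.5)
        assert res.quadratic_improves

    def test_saturating_curve_yields_negative_quadratic(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(8, 30, 300)
        y = np.minimum(x, 19) * 0.05 + rng.normal(0, 0.05, 300)
        res = fit_linear_quadratic(x, y)
        assert res.quadratic["x2"]["coef"] < 0
        assert res.quadratic_improves

    def test_rank_deficiency_detected(self):
        with pytest.raises(ValueError):
            fit_linear_quadratic(np.ones(10), np.arange(10.0))

    def test_covariate_absorbs_confounded_effect(self):
        # y depends only on age; a puberty proxy correlated with age shows an
        # effect alone but not once age is controlled
        rng = np.random.default_rng(5)
        age = rng.uniform(8, 18, 200)
        pds = age * 0.3 + rng.normal(0, 0.5, 200)
        y = 0.1 * age + rng.normal(0, 0.2, 200)
        alone = fit_linear_quadratic(pds, y)
        assert alone.linear["x"]["p"] < 0.01
        controlled = fit_linear_quadratic(pds, y, covariates=age)
        assert controlled.linear["x"]["p"] > 0.05


class TestTwoLine:
    def test_planted_breakpoint_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(8, 30, 300)
        y = np.where(x < 19, 0.1 * (x - 19), 0.0) + rng.normal(0, 0.05, 300)
        res = two_line_regression(x, y)
        assert abs(res.breakpoint - 19) < 2.5
        assert res.p_low < 1e-4 and res.slope_low == pytest.approx(0.1, abs=0.03)
        assert res.p_high > 0.05
        assert not res.sign_change

    def test_globally_linear_data_same_sign_slopes(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 200)
        y = 0.5 * x + rng.normal(0, 0.1, 200)
        res = two_line_regression(x, y)
        assert np.sign(res.slope_low) == np.sign(res.slope_high)
        assert not res.sign_change

    def test_true_inverted_u_certified(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-5, 5, 300)
        y = -x**2 + rng.normal(0, 0.5, 300)
        res = two_line_regression(x, y)
        assert res.sign_change
        assert res.slope_low > 0 > res.slope_high

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            two_line_regression(np.ones(20), np.arange(20.0))


class TestAgeBinning:
    def test_six_groups_with_balanced_under18_quartiles(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "age": np.r_[rng.uniform(8, 18, 160), rng.uniform(18, 25, 40),
                         rng.uniform(25, 30, 40)],
            "sex": rng.integers(0, 2, 240),
        })
        labels = bin_by_age(df)
        counts = labels.value_counts()
        for q in ("u18_q1", "u18_q2", "u18_q3", "u18_q4"):
            assert 36 <= counts[q] <= 44
        assert counts["18-25"] == 40 and counts["25-30"] == 40

    def test_adults_only_populates_two_groups(self):
        df = pd.DataFrame({"age": np.linspace(18, 30, 30),
                           "sex": [0, 1] * 15})
        labels = bin_by_age(df)
        assert set(labels) == {"18-25", "25-30"}

    def test_quartile_boundaries_near_expected_for_uniform_ages(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"age": rng.uniform(8, 18, 400),
                           "sex": rng.integers(0, 2, 400)})
        labels = bin_by_age(df)
        b1 = df.loc[labels == "u18_q1", "age"].max()
        b2 = df.loc[labels == "u18_q2", "age"].max()
        b3 = df.loc[labels == "u18_q3", "age"].max()
        assert abs(b1 - 10.5) < 1 and abs(b2 - 13) < 1 and abs(b3 - 15.5) < 1
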