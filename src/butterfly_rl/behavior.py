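"""Model-independent analyses and exclusion criteria.

Covers per-participant summaries (block accuracies, log-odds performance,
reaction-time transforms, win-stay behavior, data-quality metrics), the
exclusion rules (switch-more-than-stay after a win; worse-than-chance combined
with a low-data-quality flag; near-complete missingness), trial-level
reward-history and delay regressors, the mixed-effects logistic regression of
correct choice on those regressors, linear/quadratic regression with a
sequential F-test, two-line (interrupted) regression for certifying U shapes,
and the six-group age binning used for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._laplace_glmm import fit_laplace_glmm
from .synthetic_cohort import CohortData
from .task_env import TrialData


@dataclass(frozen=True)
class ExclusionThresholds:
    """Fixed documented stand-ins for the elbow-point rules."""

    same_choice_prop: float = 0.95
    change_prop: float = 0.95
    longest_run: int = 40
    missing_prop: float = 0.5


@dataclass
class BehaviorSummary:
    participant_id: str
    block_accuracy: np.ndarray
    p_correct: float
    log_odds: float
    median_rt: float
    sd_rt: float
    log_median_rt: float
    stay_after_win: float
    switch_after_win: float
    same_choice_prop: float
    change_prop: float
    longest_same_choice_run: int
    missing_prop: float
    n_valid: int


def summarize(trial_data: TrialData, n_blocks: int = 4) -> BehaviorSummary:
    """Per-participant behavioral summary; missing trials excluded from
    accuracy/RT but counted in the missing proportion."""
    trial_data.validate()
    ok = ~trial_data.missing.astype(bool)
    n_valid = int(ok.sum())
    if n_valid == 0:
        raise ValueError(f"all trials missing for {trial_data.participant_id}")
    correct = trial_data.correct
    n = trial_data.n_trials

    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    block_acc = np.array([
        correct[lo:hi][ok[lo:hi]].mean() if ok[lo:hi].any() else np.nan
        for lo, hi in zip(edges[:-1], edges[1:])
    ])
    k = int(correct[ok].sum())
    p = k / n_valid
    # Haldane-style correction keeps the log-odds finite at p in {0, 1}
    p_adj = (k + 0.5) / (n_valid + 1) if p in (0.0, 1.0) else p
    log_odds = float(np.log(p_adj / (1 - p_adj)))

    rts = trial_data.rt[ok]
    rts = rts[np.isfinite(rts)]
    median_rt = float(np.median(rts)) if len(rts) else np.nan
    sd_rt = float(np.std(rts, ddof=1)) if len(rts) > 1 else np.nan
    log_median_rt = float(np.log(median_rt)) if median_rt and median_rt > 0 else np.nan

    stay, switch = _stay_switch_after_win(trial_data)
    same, change, run = _choice_dynamics(trial_data)
    return BehaviorSummary(
        participant_id=trial_data.participant_id,
        block_accuracy=block_acc,
        p_correct=p,
        log_odds=log_odds,
        median_rt=median_rt,
        sd_rt=sd_rt,
        log_median_rt=log_median_rt,
        stay_after_win=stay,
        switch_after_win=switch,
        same_choice_prop=same,
        change_prop=change,
        longest_same_choice_run=run,
        missing_prop=float(trial_data.missing.mean()),
        n_valid=n_valid,
    )


def _stay_switch_after_win(td: TrialData) -> tuple[float, float]:
    """Stay/switch proportions on the next encounter of the same stimulus
    after a rewarded choice of it."""
    ok = ~td.missing.astype(bool)
    n_stay = n_switch = 0
    last_choice = {}
    last_rewarded = {}
    for t in range(td.n_trials):
        if not ok[t]:
            continue
        s = int(td.stimulus[t])
        if s in last_choice and last_rewarded[s]:
            if td.action[t] == last_choice[s]:
                n_stay += 1
            else:
                n_switch += 1
        last_choice[s] = int(td.action[t])
        last_rewarded[s] = bool(td.reward[t])
    total = n_stay + n_switch
    if total == 0:
        return np.nan, np.nan
    return n_stay / total, n_switch / total


def _choice_dynamics(td: TrialData) -> tuple[float, float, int]:
    """Same-choice / changed-choice proportions over consecutive valid trials
    (any stimulus) and the longest run of one repeated flower choice."""
    acts = td.action[~td.missing.astype(bool)]
    if len(acts) < 2:
        return np.nan, np.nan, len(acts)
    same = float((acts[1:] == acts[:-1]).mean())
    run = best = 1
    for a, b in zip(acts[:-1], acts[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return same, 1.0 - same, best


def summarize_cohort(cohort: CohortData) -> pd.DataFrame:
    rows = []
    for td in cohort.sessions:
        try:
            s = summarize(td)
        except ValueError:
            rows.append(dict(participant=td.participant_id, all_missing=True,
                             missing_prop=1.0))
            continue
        d = {k: v for k, v in vars(s).items() if k != "block_accuracy"}
        d["participant"] = d.pop("participant_id")
        d["all_missing"] = False
        for b, v in enumerate(s.block_accuracy):
            d[f"block{b + 1}_accuracy"] = v
        rows.append(d)
    return pd.DataFrame(rows)


def apply_exclusions(cohort: CohortData,
                     thresholds: ExclusionThresholds = ExclusionThresholds(),
                     ) -> tuple[CohortData, pd.DataFrame]:
    """Apply the exclusion rules; returns (kept cohort, per-participant report).

    Rules: (a) switch-after-win exceeds stay-after-win; (b) worse than chance
    AND at least one low-data-quality flag (same-choice, change, longest-run,
    missing); (c) near-complete missingness on its own.
    """
    summaries = summarize_cohort(cohort)
    reasons = []
    for _, row in summaries.iterrows():
        r = []
        if row.get("all_missing", False):
            r.append("all_missing")
        else:
            if row["missing_prop"] > thresholds.missing_prop:
                r.append("missing")
            if np.isfinite(row["switch_after_win"]) and \
                    row["switch_after_win"] > row["stay_after_win"]:
                r.append("switch_gt_stay")
            flags = []
            if row["same_choice_prop"] > thresholds.same_choice_prop:
                flags.append("same_choice")
            if row["change_prop"] > thresholds.change_prop:
                flags.append("change")
            if row["longest_same_choice_run"] > thresholds.longest_run:
                flags.append("long_run")
            if row["missing_prop"] > thresholds.missing_prop:
                flags.append("missing")
            if row["p_correct"] < 0.5 and flags:
                r.append("below_chance+" + "|".join(flags))
        reasons.append(";".join(r))
    report = summaries.copy()
    report["excluded"] = [bool(r) for r in reasons]
    report["reason"] = reasons
    kept = cohort.subset(~report["excluded"].to_numpy())
    return kept, report


def compute_regressors(trial_data: TrialData) -> pd.DataFrame:
    """Trial-level reward-history and delay regressors.

    ``r`` counts prior Win feedbacks for the current stimulus; ``d`` counts
    the trials strictly between the current trial and the last same-stimulus
    encounter that ended in reward (so consecutive encounters give d = 0;
    undefined before the first such reward — those rows are flagged
    ``included=False``). z-scored copies are computed over included rows only.
    """
    ok = ~trial_data.missing.astype(bool)
    correct = trial_data.correct
    rows = []
    wins = {}
    last_reward_t = {}
    for t in range(trial_data.n_trials):
        if not ok[t]:
            continue
        s = int(trial_data.stimulus[t])
        r = wins.get(s, 0)
        if s in last_reward_t:
            d, included = t - last_reward_t[s] - 1, True
        else:
            d, included = np.nan, False
        rows.append(dict(trial=t, stimulus=s, r=r, d=d, correct=int(correct[t]),
                         included=included))
        if trial_data.reward[t] == 1:
            wins[s] = r + 1
            last_reward_t[s] = t
    df = pd.DataFrame(rows)
    if len(df):
        inc = df["included"]
        for col in ("r", "d"):
            z = np.full(len(df), np.nan)
            vals = df.loc[inc, col].to_numpy(float)
            sd = vals.std(ddof=0) if inc.any() else 0.0
            if sd > 0:
                z[inc.to_numpy()] = (vals - vals.mean()) / sd
            elif inc.any():
                z[inc.to_numpy()] = 0.0
            df[f"z_{col}"] = z
    return df


@dataclass
class MixedLogisticResult:
    fixed_effects: dict
    se: dict
    z: dict
    p: dict
    random_effects: pd.DataFrame  # conditional (fixed + mode) per participant
    Sigma: np.ndarray
    loglik: float
    converged: bool


def fit_mixed_logistic(regressor_tables: dict[str, pd.DataFrame],
                       zscore_pooled: bool = True) -> MixedLogisticResult:
    """Mixed-effects logistic regression of correct choice on reward history
    and delay: correct ~ 1 + r + d + (1 + r + d | participant).

    ``regressor_tables`` maps participant id to :func:`compute_regressors`
    output. Regressors are z-scored over the pooled included rows by default.
    Rows with undefined delay are dropped.
    """
    pids, frames = [], []
    for pid, df in regressor_tables.items():
        sub = df[df["included"]].copy()
        if len(sub):
            sub["participant"] = pid
            frames.append(sub)
    if len(frames) < 2:
        raise ValueError("need >= 2 participants with defined rows")
    pooled = pd.concat(frames, ignore_index=True)
    if zscore_pooled:
        for col in ("r", "d"):
            v = pooled[col].to_numpy(float)
            pooled[f"z_{col}"] = (v - v.mean()) / v.std(ddof=0)

    Xs, ys, used = [], [], []
    for pid, sub in pooled.groupby("participant", sort=True):
        X = np.column_stack([np.ones(len(sub)), sub["z_r"], sub["z_d"]])
        Xs.append(X)
        ys.append(sub["correct"].to_numpy(float))
        used.append(pid)
    fit = fit_laplace_glmm(Xs, ys)
    names = ("intercept", "r", "d")
    beta, se = fit["beta"], fit["se"]
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    ranef = pd.DataFrame(fit["random_modes"] + beta[None, :],
                         columns=[f"effect_{n}" for n in names])
    ranef.insert(0, "participant", used)
    return MixedLogisticResult(
        fixed_effects=dict(zip(names, beta)),
        se=dict(zip(names, se)),
        z=dict(zip(names, z)),
        p=dict(zip(names, p)),
        random_effects=ranef,
        Sigma=fit["Sigma"],
        loglik=fit["loglik"],
        converged=fit["converged"],
    )


@dataclass
class LinQuadResult:
    linear: dict          # coef, ci_low, ci_high per term
    quadratic: dict
    f_stat: float
    f_p: float
    quadratic_improves: bool
    linear_model: object = field(repr=False, default=None)
    quadratic_model: object = field(repr=False, default=None)


def fit_linear_quadratic(x, y, covariates: np.ndarray | None = None,
                         alpha: float = 0.05) -> LinQuadResult:
    """OLS of y on x and on (x, x^2), with a sequential F-test for the
    quadratic term; optional extra covariate columns enter both models."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != len(x):
            covariates = covariates.T
        keep &= np.isfinite(covariates).all(axis=1)
        covariates = covariates[keep]
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValueError("need n >= 4")

    def design(deg):
        cols = [np.ones_like(x), x]
        names = ["intercept", "x"]
        if deg == 2:
            cols.append(x**2)
            names.append("x2")
        if covariates is not None:
            for i in range(covariates.shape[1]):
                cols.append(covariates[:, i])
                names.append(f"cov{i}")
        return np.column_stack(cols), names

    X1, names1 = design(1)
    X2, names2 = design(2)
    if np.linalg.matrix_rank(X2) < X2.shape[1]:
        raise ValueError("rank-deficient design")
    m1 = sm.OLS(y, X1).fit()
    m2 = sm.OLS(y, X2).fit()
    f_stat, f_p, _ = m2.compare_f_test(m1)

    def pack(m, names):
        ci = m.conf_int(alpha)
        return {n: dict(coef=float(m.params[i]), ci_low=float(ci[i][0]),
                        ci_high=float(ci[i][1]), p=float(m.pvalues[i]))
                for i, n in enumerate(names)}

    return LinQuadResult(
        linear=pack(m1, names1),
        quadratic=pack(m2, names2),
        f_stat=float(f_stat),
        f_p=float(f_p),
        quadratic_improves=bool(f_p < alpha),
        linear_model=m1,
        quadratic_model=m2,
    )


@dataclass
class TwoLineResult:
    breakpoint: float
    slope_low: float
    z_low: float
    p_low: float
    slope_high: float
    z_high: float
    p_high: float
    sign_change: bool


def two_line_regression(x, y, n_candidates: int = 21,
                        quantile_range: tuple = (0.15, 0.85)) -> TwoLineResult:
    """Interrupted regression with a data-selected breakpoint.

    Fits y = b0 + b1*min(x-c, 0) + b2*max(x-c, 0) over a grid of candidate
    breakpoints c at interior x-quantiles, keeps the c minimizing SSE, and
    reports the low-segment slope b1 and high-segment slope b2 with Wald z
    statistics. A certified (inverse-)U requires both slopes significant with
    opposite signs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 8 or np.ptp(x) == 0:
        raise ValueError("need n >= 8 with spread in x")
    qs = np.linspace(*quantile_range, n_candidates)
    cands = np.unique(np.quantile(x, qs))
    cands = [c for c in cands if (x < c).sum() >= 3 and (x > c).sum() >= 3]
    if not cands:
        raise ValueError("no candidate breakpoint with points on both sides")

    best = None
    for c in cands:
        X = np.column_stack([np.ones_like(x), np.minimum(x - c, 0), np.maximum(x - c, 0)])
        m = sm.OLS(y, X).fit()
        if best is None or m.ssr < best[1].ssr:
            best = (c, m)
    c, m = best
    b1, b2 = m.params[1], m.params[2]
    z1, z2 = m.tvalues[1], m.tvalues[2]
    p1, p2 = m.pvalues[1], m.pvalues[2]
    return TwoLineResult(
        breakpoint=float(c),
        slope_low=float(b1), z_low=float(z1), p_low=float(p1),
        slope_high=float(b2), z_high=float(z2), p_high=float(p2),
        sign_change=bool(np.sign(b1) != np.sign(b2) and p1 < 0.05 and p2 < 0.05),
    )


AGE_GROUP_LABELS = ("u18_q1", "u18_q2", "u18_q3", "u18_q4", "18-25", "25-30")


def bin_by_age(participants: pd.DataFrame, n_bins_under_18: int = 4) -> pd.Series:
    """Six age groups: under-18s split into sex-wise quartiles (then merged
    across sex by quartile rank), plus fixed 18-25 and 25-30 groups."""
    ages = participants["age"]
    sex = participants["sex"]
    under = ages < 18
    if under.sum() > 0 and under.sum() < 2 * n_bins_under_18:
        raise ValueError("too few under-18 participants to form quartiles")
    labels = pd.Series(index=participants.index, dtype=object)
    for s in sex[under].unique():
        mask = under & (sex == s)
        if mask.sum() >= n_bins_under_18:
            q = pd.qcut(ages[mask], n_bins_under_18, labels=False, duplicates="drop")
            labels[mask] = [AGE_GROUP_LABELS[int(v)] for v in q]
        else:
            labels[mask] = AGE_GROUP_LABELS[0]
    labels[(ages >= 18) & (ages < 25)] = "18-25"
    labels[ages >= 25] = "25-30"
    return labels
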