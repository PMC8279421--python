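# Methods

## The task

The Butterfly task is a contextual two-armed bandit. Four stimuli
("butterflies") are each shown 30 times in a pre-randomized interleaved order
(120 trials). Each stimulus has one fixed preferred action ("flower").
Choosing it yields reward with probability 0.8; on the remaining 20% of
trials the *other* action is the rewarded one. The schedule is implemented as
one Bernoulli(0.8) draw per trial indicating which action pays out — not
independent draws per action — so an oracle agent earns exactly the drawn
rate and an anti-oracle earns its complement. The stimulus order is a seeded
permutation with at most four consecutive repeats of one stimulus (the cap
avoids pathological runs and is configurable); reward draws are free
Bernoulli by default, with an optional exact-count mode (24/30 rewarded per
stimulus). The 7 s response window is stored as design metadata; the
simulator never produces missed responses itself — the cohort generator
injects them.

## The models

Six Q-learning variants share four primitives. Q values over
(stimulus, action) pairs start at the uninformative 0.5. Choice follows a
softmax with inverse temperature β on the current stimulus's Q row
(computed with max-subtraction; exact to ~1e-12 of the naive formula).
After feedback r ∈ {0, 1} the chosen pair updates by the delta rule
Q ← Q + α·(r − Q), with α = α⁺ when the prediction error is positive and
α⁻ otherwise (a zero prediction error routes to α⁻, which is
inconsequential). Models with forgetting then decay every *other* pair
toward 0.5 at rate f. The variants fix subsets: `ab` (single α, no
forgetting), `apanb` (α⁺/α⁻), `apos0b` (α⁻ = 0), `abf`, `apanbf`,
`apos0bf` — so each nests inside `apanbf`, and the nesting identities are
tested to machine precision.

Per-trial order of operations: evaluate the choice probability on the
pre-update Q state, update the chosen pair, then apply forgetting. On a
missed trial there is no likelihood term and no delta update, but forgetting
still applies — it models the passage of trials, not the act of choosing.
This choice is configurable in principle but is the package default.

## Hierarchical estimation

Individual parameters are drawn from truncated-normal group distributions:
θ_jk ~ Normal(m_jk, σ_k) truncated to the parameter's natural range ([0, 1]
for learning rates and forgetting; [0, β_max] for β, with β_max = 30).
Without covariates m_jk is a group mean with a uniform hyperprior over the
same range; group sds have uniform hyperpriors on (0, 1] (unit-range
parameters) and (0, 10] (β). The β bounds and sd caps are package defaults
(documented, configurable): the natural range of a softmax temperature is
unbounded, and 30 already produces effectively deterministic choice on this
task. In the age-regression variant the group mean becomes
intercept + b₁·z(age) (+ b₂·z(age)²), where age is z-scored with the
analyzed sample's mean/sd (stored with the fit); non-intercept coefficients
get zero-mean normal priors with sd = half the parameter's range — weakly
informative relative to any observed effect.

### Sampler

Sampling uses an authored adaptive Metropolis-within-Gibbs kernel over a
numba-compiled trial-loop likelihood. One sweep performs:

1. component-wise Gaussian random-walk updates of every individual
   parameter (one session-likelihood evaluation per proposal);
2. component-wise updates of every group coefficient and sd (truncated-
   normal density terms only — the truncation normalization is included,
   since the group parameters are themselves sampled);
3. *group translation moves*: a proposed shift δ of one group coefficient
   applied simultaneously to every individual value along that covariate's
   direction (θ_jk += X_jp·δ);
4. a *group scale move*: σ_k and the spread of all θ_jk around their means
   rescaled together by a common factor c, accepted with the
   (n+1)·log c Jacobian term;
5. an *adaptive joint group move*: a correlated proposal over
   (coefficients, log σ_k) drawn from a covariance estimated during warmup,
   with individuals recentered and rescaled conditionally.

Moves 3–5 exist because the plain conditional scheme stalls on the
hierarchical funnel: the group location/scale and the individual values
drift along a ridge and split-R̂ plateaus above 1.05. With them, a
20-participant fit of the winning model reaches max split-R̂ ≈ 1.01–1.03
and min ESS ≈ 300+ at the default draw count. All proposal scales adapt
during warmup by Robbins–Monro toward 0.4 acceptance (0.25 for the joint
move); adaptation freezes at the end of warmup, so retained draws come from
a fixed kernel. Metropolis kernels have no divergent transitions; the
divergence count in the diagnostics is identically zero and is reported for
interface completeness.

Defaults follow the reference configuration: 4 chains, 4000 retained draws
per chain (16 000 total) after 1000 warmup units, with thinning 5 — i.e.
5000 warmup sweeps and 20 000 post-warmup sweeps per chain. Convergence is
declared when max split-R̂ < 1.05 and min ESS > 25 × n_chains over all free
parameters (individual and group), computed with arviz's rank-normalized
estimators. Bit-reproducibility holds per (package version, seed).

### Per-subject maximum likelihood

`fit_mle_per_subject` maximizes the session likelihood with L-BFGS-B under
box bounds, 10 uniform random restarts by default. It backs the flat BIC
comparison and the posterior-predictive driver. A single 120-trial session
identifies three-parameter variants weakly (see Limitations); the
single-learning-rate forgetting model `abf` is fitted this way in the
analysis drivers rather than hierarchically.

## Model comparison

WAIC is computed from pointwise log-likelihoods whose unit is one
non-missing trial (the hierarchical likelihood factorizes by trial):
lppd_i = log mean_d exp(ll_di), p_waic_i = var_d(ll_di),
WAIC = −2·Σ(lppd_i − p_waic_i). BIC per participant is k·ln n − 2·max
log-likelihood with n = non-missing trials. Model identifiability is
summarized as a winner-count confusion matrix over generate-and-recover
replicates (protected exceedance probability is out of scope; it would need
a group-level Bayesian model-selection layer the pipeline does not define).
Ties break toward fewer free parameters.

## Synthetic cohort

The generator emulates the study conditions downstream stages assume:
ages 8–30 with 8–18 oversampled ~2:1; parameters drawn from truncated
normals whose means follow linear + quadratic trends in z-scored age
(defaults: α⁺ intercept 0.18 — the fitted group scale — with positive
linear and negative quadratic trends; β intercept 6 trending similarly;
f intercept 0.10 with a weak negative trend); pubertal covariates (PDS, T1)
as logistic-in-age curves plus noise with a ~1-year earlier female shift —
a device for exercising the regression code, not a scientific model of
puberty (age–PDS/T1 correlations exceed 0.8 overall and collapse inside
narrow age bands, which is what the within-band testosterone analysis
requires); lognormal reaction times whose median falls with age; a
configurable missing-trial rate; and an off-task minority (default 0 in the
base config; 10% in the analysis drivers) split between uniform-random
choosers and perseverators, the two archetypes the exclusion rules target.

What the generator does *not* emulate: working-memory contributions,
within-session non-stationarity, RT–difficulty coupling, sex-specific
puberty timelines beyond the offset, and any real distribution of
parameters — no empirical generative law exists to copy. Passing tests
therefore certify
the pipeline's statistical machinery on data satisfying the model's own
assumptions, not conclusions about any empirical cohort.

## Behavioral battery

Per-participant summaries: block accuracies over four 30-trial blocks,
overall p(correct) and its log odds (Haldane-corrected, p ← (k+0.5)/(n+1),
when p ∈ {0, 1}), median/sd/log-median RT, stay- and switch-after-win
proportions (transitions between consecutive encounters of the same
stimulus following reward), same-choice and changed-choice proportions,
longest same-choice run, and missing proportion.

Exclusions: (a) switch-after-win > stay-after-win; (b) below-chance
accuracy AND at least one data-quality flag (same-choice > 0.95,
change > 0.95, longest run > 40, missing > 0.5 — fixed documented stand-ins
for the elbow-point procedure, whose exact algorithm is not restated here);
(c) missing proportion alone above threshold. The conjunctive rules are
probabilistic traps by design: a uniform-random chooser trips the switch
rule about half the time, a perseverator the below-chance+flag rule when
its fixed choices happen to be mostly wrong. Tightening any threshold can
only exclude more participants (tested).

Trial-level regressors: r = number of prior rewarded encounters of the
current stimulus; d = number of trials strictly between the current trial
and the last rewarded same-stimulus encounter (undefined before the first
reward; such rows are dropped from the regression, not imputed). Regressors
are z-scored over the pooled included rows. The mixed logistic model
p(correct) ~ 1 + r + d with correlated per-participant random intercepts
and slopes is fitted by Laplace-approximated marginal maximum likelihood
(the covariance is parametrized by its Cholesky factor; per-participant
modes found by damped Newton; fixed-effect Wald SEs conditional on the
variance parameters). The estimator agrees with lme4's glmer on shared
simulated data to ~0.02 on fixed effects and recovers planted effects to
within a few percent over replicates.

Regressions on age/puberty: OLS with a sequential F-test for the quadratic
term, optional covariate adjustment (used for the puberty-controlling-age
analyses); two-line (interrupted) regression with the breakpoint chosen by
grid search over interior x-quantiles minimizing SSE, reporting per-segment
Wald z — a documented stand-in for the cited breakpoint rule. A U shape is
certified only if both segment slopes are significant with opposite signs.
Age groups: under-18s split into sex-wise quartiles merged by rank, plus
18–25 and 25–30.

## Validation battery

Generate-and-recover simulates a cohort with known parameters, refits
(hierarchically or by MLE), and reports per-parameter Pearson/Spearman
correlation, bias, and RMSE (degenerate zero-spread inputs report NaN
correlations explicitly). The headline recovery check mirrors the source
procedure: a real study has no ground truth, so generating values are the
posterior means of a first-stage fit, which concentrates them in the
identifiable region; at n = 100 participants this yields r > 0.7 for α⁺
and β. Direct recovery from the raw generative laws at n = 50 plateaus
near r ≈ 0.65–0.69 for α⁺ — the theoretical ceiling
sqrt(1 − E[posterior var]/prior var) for 120-trial sessions sits almost
exactly at that level, so the shortfall is a property of the data volume,
not the sampler. The α⁻ check reproduces the motivation for dropping the
full asymmetric model: with α⁻ generated near 0 its recovery correlation is
statistically indistinguishable from 0, while a mid-range α⁻ (≈0.4)
recovers at r ≈ 0.6.

Age-coefficient calibration uses a well-identified regime (high β, no
forgetting, single learning rate free) so that the null false-positive rate
(~5%) and the detection rate for a strong positive linear effect probe the
regression machinery rather than the weak-identification floor; at the
default cohort regime and desk-scale n, the coefficient posterior is wide
enough that detection power is low — expected, and documented rather than
asserted.

Posterior-predictive checks simulate each participant's session 100 times
at point estimates (posterior means or MLE; full-posterior draws behind a
flag) and overlay block-accuracy curves with a 95% envelope. Performance
sweeps tabulate Monte-Carlo mean accuracy over parameter grids; they
reproduce the inverse-U of accuracy in α⁺ at moderate β, the 0.5 floor at
β = 0, and the degradation from heavy forgetting.

## Problem sizes and numerical choices

Desk-scale defaults used by the tests and the acceptance script — the
package's own choices for a single-CPU workflow: 500 sessions for the
reward-rate Monte Carlo; 20 participants at the full 16 000-draw
configuration for the convergence benchmark; 100 participants with 2-chain,
2400-retained-draw fits for the recovery check; 12 null + 6 power
replicates at n = 40 for the coefficient calibration; 20 replicates of
n = 200 participants for the mixed-logistic recovery. Likelihood kernels
are compiled with numba at first use. Softmax uses max-subtraction;
truncated-normal log-densities guard against vanishing normalization;
optimizer restarts are uniform within bounds. Ties in WAIC/BIC break toward
fewer parameters.

## Known limitations

- Random-walk MCMC needs the de-funneling group moves to converge; very
  small cohorts (n ≲ 10) with weakly informative data can still leave the
  group sd posterior diffuse and slow.
- A single 120-trial session cannot identify α⁻ near 0, β above ~10, or f
  jointly with α⁺ to better than ±0.1; every downstream claim is made at
  the hierarchy level for this reason.
- The Laplace approximation slightly biases GLMM variance components
  downward; fixed effects are accurate to a few percent at the sizes used.
- The elbow-point and two-line breakpoint procedures are documented
  stand-ins, not reimplementations of the cited algorithms.
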