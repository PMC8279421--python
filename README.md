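# butterfly-rl

A tested analysis pipeline for probabilistic reinforcement learning in the
**Butterfly task** — a contextual two-armed bandit in which each of four
stimuli has a fixed preferred action rewarded with probability 0.8 (and the
other action with probability 0.2). The package is aimed at computational
cognitive scientists who want to simulate the task, fit trial-level choice
models to developmental cohorts, and validate every inference step on
synthetic data with known ground truth.

## What it computes

Six Q-learning variants are defined over the primitives

- softmax choice  P(a|b) = exp(β·Q(b,a)) / Σᵢ exp(β·Q(b,aᵢ)),
- delta-rule update  Q ← Q + α·(r − Q), with α = α⁺ when the reward
  prediction error is positive and α⁻ otherwise,
- forgetting  Q ← (1−f)·Q + f·0.5 for every non-updated (stimulus, action)
  pair, each trial,

with Q initialized at the uninformative 0.5. The variants (`ab`, `apanb`,
`apos0b`, `abf`, `apanbf`, `apos0bf`) fix subsets of (α⁺, α⁻, β, f); the
asymmetric-with-forgetting family sets α⁻ = 0 to encode insensitivity to
negative feedback.

Individual parameters are estimated **hierarchically**: θⱼ ~ Normal(μ, σ)
truncated to the parameter's natural range, with uniform hyperpriors — or,
to test developmental effects, μ replaced by a regression
intercept + b₁·z(age) + b₂·z(age)² whose coefficients are sampled jointly.
Sampling uses an adaptive Metropolis-within-Gibbs kernel with de-funneling
group moves (see `docs/methods.md`); convergence requires max split-R̂ < 1.05
and min ESS > 25 × chains over all free parameters. Models are compared by
WAIC on trial-level pointwise log-likelihoods (and per-subject BIC for the
non-hierarchical path). A model-independent battery covers exclusion rules,
reward-history/delay regressors, a correlated-random-slopes logistic mixed
model, quadratic and two-line regressions on age, and age-group binning.
Everything runs against a synthetic-cohort generator with age-trending
parameters, age-correlated puberty covariates, and off-task archetypes.

## Worked example

```python
import numpy as np
from butterfly_rl.synthetic_cohort import GroupConfig, generate_cohort
from butterfly_rl.hierarchical_fit import fit_hierarchical, SamplerConfig, diagnostics

cohort = generate_cohort(GroupConfig(n_participants=20, seed=1), "apos0bf")
post = fit_hierarchical("apos0bf", cohort, sampler_config=SamplerConfig(seed=51))
d = diagnostics(post)
print(f"max R-hat {d.max_rhat:.3f}, min ESS {d.min_ess:.0f}, passed={d.passed}")
mu = post.draws("mu_alpha_pos")
print(f"group alpha+ mean: {mu.mean():.3f} +- {mu.std():.3f} "
      f"(generating mean {cohort.participants['true_alpha_pos'].mean():.3f})")
```

prints

```
max R-hat 1.008, min ESS 330, passed=True
group alpha+ mean: 0.151 +- 0.127 (generating mean 0.159)
```

i.e. a 20-participant synthetic cohort fitted at the default 4-chain,
16 000-draw configuration converges under the strict criteria, and the
posterior for the group-level positive learning rate brackets the value the
cohort was generated with.

The numbered scripts under `analysis/` run the full narrative — simulate and
exclude (`01`), behavioral battery (`02`–`03`), hierarchical fits (`04`),
WAIC/BIC comparison (`05`), age effects inside the hierarchy (`06`), and
validation (`07`) — writing tables under `results/`. A `butterfly-rl`
console command exposes the same stages (`simulate`, `exclude`, `behave`,
`fit`, `compare`, `recover`, `ppc`, `sweep`, `pipeline`).

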