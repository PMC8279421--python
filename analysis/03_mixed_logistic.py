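"""Trial-level mixed-effects logistic regression on the kept cohort.

Builds reward-history (r) and delay (d) regressors per trial, fits
p(correct) ~ 1 + r + d with correlated per-participant random intercepts and
slopes, and regresses the per-participant conditional effects on age.
Writes results/mixed_logistic/*.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from butterfly_rl import cli_io
from butterfly_rl.behavior import (compute_regressors, fit_linear_quadratic,
                                   fit_mixed_logistic)

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    cohort = cli_io.read_cohort(OUT / "cohort" / "kept")
    outdir = OUT / "mixed_logistic"
    outdir.mkdir(parents=True, exist_ok=True)

    tables = {td.participant_id: compute_regressors(td)
              for td in cohort.sessions}
    fit = fit_mixed_logistic(tables)
    fixed = pd.DataFrame({
        "term": list(fit.fixed_effects),
        "estimate": list(fit.fixed_effects.values()),
        "se": list(fit.se.values()),
        "z": list(fit.z.values()),
        "p": list(fit.p.values()),
    })
    fixed.to_csv(outdir / "fixed_effects.csv", index=False)
    print("fixed effects:")
    print(fixed.round(4).to_string(index=False))

    ranef = fit.random_effects.merge(cohort.participants, on="participant")
    ranef.to_csv(outdir / "random_effects.csv", index=False)

    rows = []
    for term in ("effect_r", "effect_d"):
        res = fit_linear_quadratic(ranef["age"], ranef[term])
        rows.append(dict(term=term,
                         beta_age=res.linear["x"]["coef"],
                         p_age=res.linear["x"]["p"],
                         beta_age2=res.quadratic["x2"]["coef"],
                         p_quadratic=res.f_p))
        print(f"{term} vs age: beta={res.linear['x']['coef']:.4f} "
              f"(p={res.linear['x']['p']:.3g}), quadratic p={res.f_p:.3g}")
    pd.DataFrame(rows).to_csv(outdir / "random_effects_vs_age.csv", index=False)


if __name__ == "__main__":
    sys.exit(main())
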