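"""Model-independent battery on the kept cohort.

Computes per-participant summaries, regresses overall performance (log odds)
and log median RT on age (linear + quadratic with sequential F-test), runs
two-line regression on performance vs age, and tabulates block accuracy by
the six age groups. Writes results/behavior/*.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from butterfly_rl import cli_io
from butterfly_rl.behavior import (bin_by_age, fit_linear_quadratic,
                                   summarize_cohort, two_line_regression)

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    cohort = cli_io.read_cohort(OUT / "cohort" / "kept")
    outdir = OUT / "behavior"
    outdir.mkdir(parents=True, exist_ok=True)

    summaries = summarize_cohort(cohort).merge(
        cohort.participants, on="participant")
    summaries.to_csv(outdir / "summaries.csv", index=False)

    rows = []
    for label, y in [("log_odds_correct", summaries["log_odds"]),
                     ("log_median_rt", summaries["log_median_rt"])]:
        res = fit_linear_quadratic(summaries["age"], y)
        two = two_line_regression(summaries["age"], y)
        rows.append(dict(
            outcome=label,
            beta_age=res.linear["x"]["coef"],
            beta_age_ci=f"[{res.linear['x']['ci_low']:.3f}, {res.linear['x']['ci_high']:.3f}]",
            beta_age2=res.quadratic["x2"]["coef"],
            f_quadratic=res.f_stat, p_quadratic=res.f_p,
            breakpoint=two.breakpoint,
            slope_low=two.slope_low, p_low=two.p_low,
            slope_high=two.slope_high, p_high=two.p_high))
        print(f"{label}: beta_age={res.linear['x']['coef']:.4f} "
              f"(quadratic F={res.f_stat:.1f}, p={res.f_p:.3g}); "
              f"two-line breakpoint {two.breakpoint:.1f} y, "
              f"slopes {two.slope_low:.3f} (p={two.p_low:.2g}) / "
              f"{two.slope_high:.3f} (p={two.p_high:.2g})")
    pd.DataFrame(rows).to_csv(outdir / "age_regressions.csv", index=False)

    labels = bin_by_age(summaries)
    block_cols = [c for c in summaries if c.startswith("block")]
    by_group = summaries.assign(age_group=labels).groupby("age_group")[
        block_cols + ["p_correct"]].mean()
    by_group.to_csv(outdir / "learning_curves_by_age_group.csv")
    print("\nblock accuracy by age group:")
    print(by_group.round(3).to_string())


if __name__ == "__main__":
    sys.exit(main())
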