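"""Simulate the synthetic developmental cohort and apply the exclusion rules.

Generates 120 participants (ages 8-30, 8-18 oversampled ~2:1) from the
winning forgetting model with age-trending parameters, a 10% off-task
minority, and 2% missing trials; writes the cohort CSVs, the exclusion
report, and the kept cohort under results/cohort/.
"""

import sys
from pathlib import Path

import numpy as np

from butterfly_rl import cli_io
from butterfly_rl.behavior import apply_exclusions
from butterfly_rl.synthetic_cohort import GroupConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260929


def main():
    config = GroupConfig(n_participants=120, p_off_task=0.10,
                         missing_rate=0.02, seed=SEED)
    cohort = generate_cohort(config, "apos0bf")
    cli_io.write_cohort(OUT / "cohort", cohort)

    kept, report = apply_exclusions(cohort)
    cli_io.write_cohort(OUT / "cohort" / "kept", kept)
    report.to_csv(OUT / "cohort" / "exclusion_report.csv", index=False)
    cli_io.write_manifest(OUT / "cohort", None,
                          extra={"stage": "simulate+exclude", "seed": SEED,
                                 "n": cohort.n, "kept": kept.n})

    n_off = int(cohort.participants["off_task"].sum())
    n_excl = int(report["excluded"].sum())
    print(f"cohort: {cohort.n} participants ({n_off} off-task by construction)")
    print(f"excluded: {n_excl}; kept: {kept.n}")
    print(report.loc[report["excluded"], "reason"].value_counts().to_string())


if __name__ == "__main__":
    sys.exit(main())
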