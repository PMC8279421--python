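"""Compare the fitted models: WAIC for the hierarchical fits, delta-BIC for
the per-subject fits. Writes results/comparison/*.csv."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from butterfly_rl.model_comparison import compare, compare_bic

OUT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main():
    outdir = OUT / "comparison"
    outdir.mkdir(parents=True, exist_ok=True)

    fits = {p.stem.replace("pointwise_", ""): np.load(p)
            for p in sorted(SCRATCH.glob("pointwise_*.npy"))}
    table = compare(fits)
    table.to_csv(outdir / "waic.csv", index=False)
    print("WAIC comparison (lower is better):")
    print(table.sort_values("delta_waic").round(1).to_string(index=False))

    mle = pd.read_csv(OUT / "fits" / "mle_per_subject.csv")
    bic_by_model = {m: g.sort_values("participant")["bic"].to_numpy()
                    for m, g in mle.groupby("model")}
    bic_table = compare_bic(bic_by_model, reference="apos0bf")
    bic_table.to_csv(outdir / "bic.csv", index=False)
    print("\nper-subject BIC vs apos0bf (positive delta = worse):")
    print(bic_table.round(1).to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
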