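"""Validation battery: generate-and-recover for the winning model, the
alpha- non-recoverability demonstration, posterior-predictive learning
curves, and the performance sweeps over (alpha+, beta) and forgetting.
Writes results/validation/*.csv."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from butterfly_rl import cli_io
from butterfly_rl.hierarchical_fit import SamplerConfig, fit_mle_per_subject
from butterfly_rl.rl_models import get_model
from butterfly_rl.synthetic_cohort import DEFAULT_LAWS, GroupConfig, ParamLaw
from butterfly_rl.validation import (generate_and_recover,
                                     performance_sweep, posterior_predictive)

OUT = Path(__file__).resolve().parent.parent / "results"
N_CAP = 30


def main():
    outdir = OUT / "validation"
    outdir.mkdir(parents=True, exist_ok=True)
    sc = SamplerConfig(n_chains=2, n_warmup=700, n_samples=1000, thin=3, seed=23)

    rep = generate_and_recover(
        "apos0bf", GroupConfig(n_participants=40, seed=31), "hierarchical",
        np.random.default_rng(31), sampler_config=sc)
    rep.to_frame().to_csv(outdir / "recovery_apos0bf.csv", index=False)
    print("recovery (apos0bf, hierarchical):")
    print(rep.to_frame().round(3).to_string(index=False))

    laws = {**DEFAULT_LAWS, "alpha_neg": ParamLaw(0.02, 0.0, 0.0, sd=0.02)}
    rep2 = generate_and_recover(
        "apanbf", GroupConfig(n_participants=40, seed=32, laws=laws),
        "hierarchical", np.random.default_rng(32), sampler_config=sc)
    rep2.to_frame().to_csv(outdir / "recovery_apanbf_low_alpha_neg.csv",
                           index=False)
    print("\nrecovery with alpha- generated near 0 (apanbf):")
    print(rep2.to_frame().round(3).to_string(index=False))

    # posterior predictive from per-subject MLE point estimates
    cohort = cli_io.read_cohort(OUT / "cohort" / "kept")
    cohort = cohort.subset(np.arange(cohort.n) < N_CAP)
    spec = get_model("apos0bf")
    rng = np.random.default_rng(33)
    fitted = np.array([
        [getattr(fit_mle_per_subject(spec, td, n_restarts=6, seed=7)[0], p)
         for p in spec.free_params]
        for td in cohort.sessions])
    ppc = posterior_predictive(fitted, spec, cohort, 100, rng)
    pd.DataFrame({
        "block": np.arange(1, 5),
        "observed": ppc["observed_curve"],
        "simulated": ppc["simulated_curve"],
        "envelope_low": ppc["envelope_low"],
        "envelope_high": ppc["envelope_high"],
    }).to_csv(outdir / "ppc_curves.csv", index=False)
    print("\nposterior-predictive block accuracy (observed vs simulated):")
    print(np.round(ppc["observed_curve"], 3), np.round(ppc["simulated_curve"], 3))

    grid = {"alpha_pos": np.round(np.linspace(0.05, 0.95, 10), 2),
            "beta": np.array([0.0, 2.0, 5.0, 10.0, 15.0])}
    sweep_ab = performance_sweep("apos0bf", grid, 200,
                                 np.random.default_rng(34), fixed={"f": 0.05})
    sweep_ab.to_csv(outdir / "sweep_alpha_beta.csv", index=False)
    sweep_f = performance_sweep(
        "apos0bf", {"alpha_pos": np.round(np.linspace(0.05, 0.95, 10), 2),
                    "f": np.array([0.0, 0.05, 0.1, 0.2])},
        200, np.random.default_rng(35), fixed={"beta": 8.0})
    sweep_f.to_csv(outdir / "sweep_alpha_f.csv", index=False)
    best = sweep_ab.loc[sweep_ab["global_max"]].iloc[0]
    print(f"\nsweep global max: accuracy {best['accuracy']:.3f} at "
          f"alpha+={best['alpha_pos']}, beta={best['beta']}")


if __name__ == "__main__":
    sys.exit(main())
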