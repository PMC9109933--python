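"""Replicated simulation study across the three instrument-strength regimes.

For each scenario — (a) beta_X symmetric about zero, (b) mixed signs with a
nonzero mean, (c) all positive — and each pleiotropy regime (balanced /
directional, 30% invalid instruments unless overridden), runs replicated
two-sample simulations and summarizes IVW, MR-Egger and Radial-Egger under
the oracle, default and random codings. Writes per-(scenario x regime x
method x coding) summaries to results/simulation_summary.tsv and prints the
bias table.

Defaults are scaled for a quick desk run (100 replications, n = 20,000 per
cohort); pass --n 100000 --reps 1000 for full-size runs.
"""

import argparse
from pathlib import Path

import pandas as pd

from mrorient import EffectSpec, ScenarioConfig, run_scenario

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--m", type=int, default=100)
    parser.add_argument("--n", type=int, default=20_000)
    parser.add_argument("--reps", type=int, default=100)
    parser.add_argument("--theta", type=float, default=0.2)
    parser.add_argument("--prop-invalid", type=float, default=0.3)
    parser.add_argument("--seed", type=int, default=3)
    args = parser.parse_args()

    frames = []
    for scenario in ("a", "b", "c"):
        for pleiotropy in ("balanced", "directional"):
            cfg = ScenarioConfig(
                effect_spec=EffectSpec(
                    scenario=scenario,
                    prop_invalid=args.prop_invalid,
                    pleiotropy=pleiotropy,
                ),
                m=args.m,
                n_exposure=args.n,
                n_outcome=args.n,
                theta=args.theta,
                reps=args.reps,
                seed=args.seed,
                methods=("IVW_RE", "EGGER", "RADIAL_EGGER"),
                codings=("oracle", "default", "random"),
            )
            summ = run_scenario(cfg).summary
            summ.insert(0, "scenario", scenario)
            summ.insert(1, "pleiotropy", pleiotropy)
            frames.append(summ)
            print(f"scenario ({scenario}), {pleiotropy}: done")
    table = pd.concat(frames, ignore_index=True)

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "simulation_summary.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.5g")
    print(f"\nwrote {out}\n")

    bias = table.pivot_table(
        index=["scenario", "pleiotropy"], columns=["method", "coding"], values="bias"
    )
    with pd.option_context("display.width", 200, "display.float_format", "{:8.3f}".format):
        print("bias (mean slope - theta):")
        print(bias)
    print(
        "\nReadings: IVW is unbiased whenever the oracle-coding mean pleiotropy "
        "is zero (balanced) or the mean instrument strength is zero (scenario a); "
        "MR-Egger is unbiased only under the oracle coding — except in scenario "
        "(c), where the default coding coincides with it; Radial-Egger tracks "
        "the default-coding Egger fit."
    )


if __name__ == "__main__":
    main()
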