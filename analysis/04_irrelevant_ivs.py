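"""Irrelevant instruments break the InSIDE condition even under the oracle
coding.

Appends m0 zero-strength SNPs (beta_X = 0) to each replication's instrument
set — once with pleiotropic direct effects drawn from the same law as the
relevant instruments, once with no direct effects — and compares the
oracle-coding MR-Egger bias and the equal-weight InSIDE covariance over the
padded set vs. the relevant instruments alone. Run for scenario (c)
(nonzero mean instrument strength, where padding shifts the covariance)
and scenario (a) (mean strength zero, the special case where it does not).

Writes results/irrelevant_iv_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from mrorient import EffectSpec, ScenarioConfig, irrelevant_iv_experiment

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--m", type=int, default=50)
    parser.add_argument("--m0", type=int, default=20)
    parser.add_argument("--n", type=int, default=20_000)
    parser.add_argument("--reps", type=int, default=100)
    parser.add_argument("--theta", type=float, default=0.2)
    parser.add_argument("--seed", type=int, default=4)
    args = parser.parse_args()

    frames = []
    for scenario in ("c", "a"):
        cfg = ScenarioConfig(
            effect_spec=EffectSpec(
                scenario=scenario, prop_invalid=1.0, pleiotropy="directional"
            ),
            m=args.m,
            n_exposure=args.n,
            n_outcome=args.n,
            theta=args.theta,
            reps=args.reps,
            seed=args.seed,
            methods=("EGGER",),
            codings=("oracle",),
        )
        res = irrelevant_iv_experiment(cfg, m0=args.m0)
        extra = (
            res.records.groupby("arm")[["inside_cov", "inside_cov_core"]]
            .mean()
            .rename(columns={"inside_cov": "mean_inside_cov_full",
                             "inside_cov_core": "mean_inside_cov_core"})
        )
        summ = res.summary.merge(extra, on="arm")
        summ.insert(0, "scenario", scenario)
        frames.append(summ)
        print(f"scenario ({scenario}): done")
    table = pd.concat(frames, ignore_index=True)

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "irrelevant_iv_summary.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.5g")
    print(f"\nwrote {out}\n")

    cols = ["scenario", "arm", "bias", "mean_inside_cov_full", "mean_inside_cov_core"]
    with pd.option_context("display.width", 160):
        print(table[cols].to_string(index=False, float_format="{:9.4f}".format))
    print(
        "\nReadings: in scenario (c), non-pleiotropic zero-strength padding "
        "shifts the full-set covariance off zero and biases the oracle-coding "
        "Egger slope; padding whose direct effects follow the same directional "
        "law leaves the covariance near zero on average (its means are "
        "unchanged), though any single dataset's covariance is nonzero. In "
        "scenario (a) the mean instrument strength is zero and padding is "
        "harmless in expectation."
    )


if __name__ == "__main__":
    main()
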