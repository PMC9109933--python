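"""Type-I error of the MR-Egger intercept test across coding schemes.

With all instruments valid (no pleiotropy), the Egger intercept is zero
under every orientation, so the 5%-level test of H0: intercept = 0 should
reject at the nominal rate whatever coding is used. Simulates replicated
null datasets and reports the empirical rejection rate under the oracle,
default and per-replication random codings.

Writes results/intercept_calibration.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from mrorient import EffectSpec, ScenarioConfig, run_scenario

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--m", type=int, default=50)
    parser.add_argument("--n", type=int, default=10_000)
    parser.add_argument("--reps", type=int, default=500)
    parser.add_argument("--seed", type=int, default=5)
    args = parser.parse_args()

    cfg = ScenarioConfig(
        effect_spec=EffectSpec(scenario="b", prop_invalid=0.0),
        m=args.m,
        n_exposure=args.n,
        n_outcome=args.n,
        theta=0.0,
        reps=args.reps,
        seed=args.seed,
        methods=("EGGER",),
        codings=("oracle", "default", "random"),
    )
    rec = run_scenario(cfg).records
    table = (
        rec.groupby("coding")
        .agg(
            rejection_rate=("intercept_p", lambda p: float((p < 0.05).mean())),
            mean_abs_intercept=("intercept", lambda x: float(x.abs().mean())),
            mean_intercept_se=("intercept_se", "mean"),
        )
        .reset_index()
    )

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "intercept_calibration.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.5g")
    print(f"wrote {out}\n")
    print(table.to_string(index=False, float_format="{:8.4f}".format))
    mc = (0.05 * 0.95 / args.reps) ** 0.5
    print(
        f"\nAll rates should sit within ~{3 * mc:.3f} of 0.05 "
        f"(3 binomial MC-SEs at {args.reps} replications). Note the default "
        "coding's larger |intercept| estimates come with larger SEs."
    )


if __name__ == "__main__":
    main()
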