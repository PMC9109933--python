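"""Simulate one two-sample MR dataset and fit all estimators under
different orientations.

Generates a single replication of the nonzero-mean-instrument-strength
set-up (scenario "b": beta_X uniform on (-0.1,-0.03) u (0.1,0.2)) with 30%
invalid instruments carrying directional pleiotropy and theta = 0.2, writes
the harmonized summary statistics to results/example_summary.tsv, and
prints IVW / MR-Egger / Radial-Egger estimates under the oracle and default
codings together with the I^2 diagnostic. The point to notice: IVW is
identical in both columns, while the Egger slope and intercept move with
the orientation.
"""

import argparse
from pathlib import Path

from mrorient import (
    EffectSpec,
    apply_coding,
    default_coding,
    draw_true_model,
    egger,
    ivw,
    nome_i_squared,
    radial_egger,
    simulate_two_sample,
    write_summary_tsv,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--m", type=int, default=100)
    parser.add_argument("--n", type=int, default=50_000)
    parser.add_argument("--theta", type=float, default=0.2)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    spec = EffectSpec(scenario="b", prop_invalid=0.3, pleiotropy="directional")
    model = draw_true_model(spec, args.m, args.theta, seed=args.seed)
    data = simulate_two_sample(model, args.n, args.n, seed=args.seed + 1)

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "example_summary.tsv"
    write_summary_tsv(data, out)
    print(f"wrote {out} (m={data.m} SNPs, n={args.n:,} per cohort, theta={args.theta})\n")

    coded = apply_coding(data, default_coding(data))
    print(f"{'':14s}{'oracle coding':>22s}{'default coding':>22s}")
    for name, fn in [("IVW(RE)", ivw), ("MR-Egger", egger), ("Radial-Egger", radial_egger)]:
        fo, fd = fn(data), fn(coded)
        print(
            f"{name:14s}{fo.slope:10.4f} (p={fo.slope_p:.3f}) "
            f"{fd.slope:12.4f} (p={fd.slope_p:.3f})"
        )
    ego, egd = egger(data), egger(coded)
    print(
        f"{'Egger intercept':14s}{ego.intercept:10.4f} (p={ego.intercept_p:.3f}) "
        f"{egd.intercept:12.4f} (p={egd.intercept_p:.3f})"
    )
    i2o = nome_i_squared(data.beta_exposure, data.se_exposure).i_squared
    i2d = nome_i_squared(coded.beta_exposure, coded.se_exposure).i_squared
    print(f"{'I^2':14s}{i2o:10.4f}{'':11s}{i2d:12.4f}")
    print(
        "\nIVW is orientation-invariant; the Egger slope/intercept and the "
        "NOME diagnostic I^2 are not."
    )


if __name__ == "__main__":
    main()
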