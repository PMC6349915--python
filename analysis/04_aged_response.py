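#!/usr/bin/env python
"""Aged-biofilm susceptibility: post-pulse live ratio vs biofilm age.

For each irrigant, biofilms of age 1-56 days receive 1- and 3-minute
pulses; the live ratio immediately after the pulse quantifies how EPS
accumulation shields mature films.  Writes results/age_response.tsv and
reports the maturation age (first weekly age with <5% change to the next).
"""

from pathlib import Path

import oralbiofilm as ob

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = {a: ob.load_parameters(f"aged/{a}") for a in ("CHX", "IPI", "NaOCl")}
    table = ob.run_age_response_study(params)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "age_response.tsv", sep="\t", index=False,
                 float_format="%.10g")
    pivot = table.pivot_table(index="age_days", columns=["agent", "pulse_s"],
                              values="live_ratio")
    print(pivot.round(4).to_string())

    weekly = ob.run_age_response_study(params, age_grid_days=[7 * k for k in range(1, 9)],
                                       pulse_durations_s=(180.0,))
    for agent in params:
        week = ob.maturation_week(weekly, agent, 180.0)
        print(f"{agent}: post-3-min-pulse response becomes age-insensitive "
              f"(<5%/week) from week {week}")


if __name__ == "__main__":
    main()
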