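#!/usr/bin/env python
"""Component trajectories with and without a 10-min CHX treatment (donor 1).

Pairs the treated and untreated arms on a shared post-treatment time axis
and reports what each component does: the dead pool surges then drains,
EPS sits at its plateau throughout, and the quorum-sensing signal and
growth factor in the treated arm stay below the control.  Writes
results/components_donor1_chx.tsv.
"""

from pathlib import Path

import numpy as np

import oralbiofilm as ob
from oralbiofilm.experiments import run_component_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = ob.load_parameters("recovery/donor1/CHX")
    result = run_component_study(params)
    frame = result.frame()
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "components_donor1_chx.tsv", sep="\t", index=False,
                 float_format="%.10g")
    t, u = result.treated, result.untreated
    d_peak_day = t.times_days[int(np.argmax(t.column("D")))]
    q_gap = np.max(u.column("Q") - t.column("Q"))
    print(f"dead-cell volume fraction peaks {d_peak_day:.1f} days after "
          f"treatment at {t.column('D').max():.4f}")
    print(f"EPS stays within {abs(t.column('E') - params.E_max).max():.2e} "
          f"of its plateau E_max={params.E_max}")
    print(f"treated growth factor trails the control by up to {q_gap:.2e} kg/m^3; "
          f"it never exceeds the control at any time point: "
          f"{bool(np.all(t.column('Q') <= u.column('Q') + 1e-15))}")


if __name__ == "__main__":
    main()
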