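#!/usr/bin/env python
"""Interval-time sweep: how acquisition rate biases apparent residence times.

Runs the full simulate -> link -> classify -> correct -> fit pipeline at
frame intervals from 30 ms to 2.5 s (10 ms exposure, fixed 120 s movies,
true T_s = 10 s) and tabulates the apparent kinetics.  With the
per-exposure bleaching probability fixed, short intervals bleach and blink
away the long binding events (underestimating T_s) while long intervals
lose the fast population entirely, so the apparent slow residence time
grows monotonically with the interval — a sampling artifact, not biology.
"""

import argparse
from pathlib import Path

from smtrack import AcquisitionConfig, KineticParams, interval_sweep
from smtrack.tables import write_table

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", type=Path, default=Path("results"))
ap.add_argument("--n-cells", type=int, default=6)
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

table = interval_sweep(KineticParams(T_s=10.0), AcquisitionConfig(),
                       [0.03, 0.1, 0.2, 0.5, 1.0, 1.5, 2.0, 2.5],
                       n_cells=args.n_cells, n_molecules=60, seed=args.seed)
write_table(table, args.out / "interval_sweep.tsv",
            units={"interval_s": "s", "T_ns_s/T_s_s": "s"})
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\napparent T_s rises with the interval although the underlying "
      "kinetics never change; tracks per cell fall because fewer frames "
      "fit in the fixed movie duration and free molecules outrun the "
      "4-px linking radius. Once the interval dwarfs T_ns the F-test "
      "finds a single component sufficient.")
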