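#!/usr/bin/env python
"""Bleach-corrected residence-time recovery and model selection.

For each seed: draw 10^4 binding dwells (F_ns 0.8, T_ns 0.5 s, T_s 5 s),
truncate them by exposure-limited photobleaching, characterize the bleach
decay from the cohort's frame-dependent counts, divide the survival
histogram by it, and refit the two-component model.  Also runs the F-test
selection on single- and two-component truth to confirm the chosen order.
"""

import argparse
import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from smtrack import KineticParams
from smtrack.tables import write_table
from smtrack.validation import dwell_recovery, model_selection_run

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", type=Path, default=Path("results"))
ap.add_argument("--n-seeds", type=int, default=20)
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

params = KineticParams()
rows = []
for k in range(args.n_seeds):
    rec = dwell_recovery(params, n_dwells=10_000, interval_s=0.2,
                         seed=args.seed + k)
    rows.append({"seed": args.seed + k, "n_observed": rec.n_observed,
                 "T_ns_fit_s": rec.fit.T_ns, "T_s_fit_s": rec.fit.T_s,
                 "F_ns_fit": rec.fit.F_ns,
                 "T_s_rel_error": rec.t_s_error_rel,
                 "F_ns_abs_error": rec.f_ns_error})
table = pd.DataFrame(rows)
write_table(table, args.out / "residence_time_recovery.tsv",
            units={"T_ns_fit_s/T_s_fit_s": "s"})
print(f"recovery over {args.n_seeds} seeds (truth T_s = {params.T_s} s, "
      f"F_ns = {params.p_ns}):")
print(f"  median T_s  {table.T_s_fit_s.median():.2f} s "
      f"(median relative error {table.T_s_rel_error.median():.1%})")
print(f"  median F_ns {table.F_ns_fit.median():.3f} "
      f"(median absolute error {table.F_ns_abs_error.median():.4f})")

single = dataclasses.replace(params, p_ns=0.0, p_s=1.0)
orders_1 = [model_selection_run(single, seed=args.seed + k).order
            for k in range(args.n_seeds)]
orders_2 = [model_selection_run(params, seed=args.seed + k).order
            for k in range(args.n_seeds)]
sel = pd.DataFrame({"seed": np.arange(args.n_seeds) + args.seed,
                    "order_single_truth": orders_1,
                    "order_mixture_truth": orders_2})
write_table(sel, args.out / "model_selection.tsv")
print(f"F-test keeps order 1 on single-exponential truth in "
      f"{orders_1.count(1)}/{args.n_seeds} seeds and picks order 2 on "
      f"two-component truth in {orders_2.count(2)}/{args.n_seeds} "
      f"(order 3 in {orders_2.count(3)})")
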