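#!/usr/bin/env python
"""Compare two simulated conditions the way imaging studies report them.

Condition A is the reference factor (specific binding: 20% of events,
T_s = 5 s).  Condition B emulates a DNA-binding-deficient variant: specific
events are rare (5%) and short (T_s = 2 s).  Each condition gets six
simulated cells; slow-population dwell distributions are compared with a
two-sample KS test and per-cell slow bound fractions with Welch's t-test.
"""

import argparse
import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from smtrack import (AcquisitionConfig, ClassifierParams, KineticParams,
                     analyze_condition, choose_nmin, ks_compare,
                     ttest_fraction)
from smtrack.compare import _analyze_cell
from smtrack.tables import write_report, write_table

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", type=Path, default=Path("results"))
ap.add_argument("--n-cells", type=int, default=6)
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

acq = AcquisitionConfig()
conditions = {
    "reference": KineticParams(),
    "dbd_deficient": dataclasses.replace(KineticParams(), p_ns=0.95, p_s=0.05,
                                         T_s=2.0),
}

results = {}
for i, (label, params) in enumerate(conditions.items()):
    rng = np.random.default_rng((args.seed, i))
    n_min = choose_nmin(acq.interval_time, params.D_free)
    classifier = ClassifierParams(n_min=n_min)
    cells, n_tracks = [], 0
    for _ in range(args.n_cells):
        dwells, bleach, stats, nt = _analyze_cell(params, acq, classifier, 60,
                                                  rng, 20.0)
        cells.append((dwells, bleach, stats))
        n_tracks += nt
    results[label] = analyze_condition(label, cells, acq.interval_time,
                                       n_tracks=n_tracks)

rows = []
for label, cond in results.items():
    fit = cond.chosen_fit
    rows.append({
        "condition": label, "n_cells": cond.n_cells, "n_tracks": cond.n_tracks,
        "n_dwells": len(cond.dwells), "order": cond.selection.order,
        "T_ns_s": fit.T_ns, "T_s_s": fit.T_s, "F_ns": fit.F_ns,
        "mean_slow_fraction": float(np.mean(cond.per_cell_slow_fraction)),
        "sd_slow_fraction": float(np.std(cond.per_cell_slow_fraction, ddof=1)),
    })
table = pd.DataFrame(rows)
write_table(table, args.out / "condition_summary.tsv",
            units={"T_ns_s/T_s_s": "s"})
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

a, b = results["reference"], results["dbd_deficient"]
ks_stat, ks_p = ks_compare(a.split.slow, b.split.slow)
t_p = ttest_fraction(a.per_cell_slow_fraction, b.per_cell_slow_fraction)
write_report({"ks_statistic": ks_stat, "ks_p": ks_p, "ttest_p": t_p,
              "n_slow_a": len(a.split.slow), "n_slow_b": len(b.split.slow)},
             args.out / "condition_comparison.txt")
print(f"\nslow-dwell KS: statistic {ks_stat:.3f}, p = {ks_p:.3g}")
print(f"per-cell slow-fraction Welch t-test: p = {t_p:.3g}")
print("the deficient condition loses most of its long-lived component, "
      "mirroring how a DNA-binding mutation collapses specific binding")
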