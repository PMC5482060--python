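#!/usr/bin/env python
"""Measure sub-pixel localization precision of the Gaussian fitter.

Renders isolated diffraction-limited spots at several photon budgets over
10 photons/px background (PSF sigma 1.2 px, 106.7 nm pixels) and reports
the RMS distance between fitted and true positions.  The reference budget
(500 photons) is the one the bound-classification thresholds assume.
"""

import argparse
from pathlib import Path

import pandas as pd

from smtrack.tables import write_table
from smtrack.validation import localization_rms_error_nm

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", type=Path, default=Path("results"))
ap.add_argument("--n-spots", type=int, default=1000)
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

rows = []
for photons in (150.0, 300.0, 500.0, 1000.0, 2000.0):
    rms = localization_rms_error_nm(n_spots=args.n_spots, photons=photons,
                                    background=10.0, psf_sigma_px=1.2,
                                    pixel_size_nm=106.7, seed=args.seed)
    rows.append({"photons": photons, "rms_error_nm": rms, "n_spots": args.n_spots})
    print(f"{photons:7.0f} photons -> RMS error {rms:6.1f} nm")

table = pd.DataFrame(rows)
write_table(table, args.out / "localization_precision.tsv",
            units={"rms_error_nm": "nm"})
ref = table.loc[table.photons == 500.0, "rms_error_nm"].iloc[0]
print(f"\nat the reference 500-photon budget the localizer is ~{ref:.0f} nm RMS,"
      f" far below the ~200 nm diffraction limit and well inside the 220 nm"
      f" frame-to-frame bound threshold")
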