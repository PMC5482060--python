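"""Tab-separated interchange tables and TIFF helpers.

Every table is written with a commented header naming units and coordinate
conventions (0-based frames, pixel-centre origin, nm derived from the
configured pixel size) so downstream stages and humans read the same
thing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "write_table", "read_table", "write_movie", "read_movie",
    "write_report", "read_report",
]

_CONVENTIONS = ("frames are 0-based; x/y are pixel-centre coordinates "
                "(origin at centre of pixel (0,0)); *_nm columns use the "
                "configured pixel size")


def write_table(df: pd.DataFrame, path, units: Optional[Dict[str, str]] = None) -> None:
    """Write a TSV with '#'-prefixed header lines documenting conventions."""
    path = Path(path)
    lines = [f"# {_CONVENTIONS}"]
    if units:
        lines.append("# units: " + "; ".join(f"{k}={v}" for k, v in units.items()))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, required: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"table {path} is missing required column '{col}'")
    return df


def write_movie(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_movie(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_report(values: Dict[str, object], path) -> None:
    """Machine-readable key=value report (one entry per line)."""
    with open(path, "w") as fh:
        for k, v in values.items():
            fh.write(f"{k}={v}\n")


def read_report(path) -> Dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line and not line.startswith("#"):
            k, _, v = line.partition("=")
            out[k] = v
    return out
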