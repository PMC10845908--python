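"""CSV serialization of interval-valued populations.

The on-disk dialect is a plain UTF-8, comma-separated, LF-terminated file
with header ``unit,x_lower,x_upper,y_lower,y_upper`` and one row per
population unit.  Unit indices are 1-based in files (survey convention) and
0-based in memory; the conversion lives entirely in this module.  Values
are written with 17 significant digits so a write/read round-trip is
lossless for finite doubles.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import NeutroArray
from .populations import NeutroPopulation

__all__ = ["read_neutro_csv", "write_neutro_csv", "COLUMNS"]

COLUMNS = ["unit", "x_lower", "x_upper", "y_lower", "y_upper"]


def read_neutro_csv(path, strict: bool = False) -> NeutroPopulation:
    """Read a population from the interval CSV dialect.

    ``strict`` additionally enforces lower <= upper element-wise on x and y.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) < 2:
        raise ValueError(f"{path}: a population needs at least 2 data rows")
    if df[COLUMNS].isna().any().any():
        raise ValueError(f"{path}: missing cells")
    units = df["unit"].to_numpy()
    if not np.issubdtype(units.dtype, np.number) or np.any(units != np.round(units)):
        raise ValueError(f"{path}: unit indices must be integers")
    if np.unique(units).size != units.size:
        raise ValueError(f"{path}: duplicate unit indices")
    vals = df[COLUMNS[1:]].apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any() or not np.all(np.isfinite(vals.to_numpy())):
        raise ValueError(f"{path}: non-numeric or non-finite values")
    order = np.argsort(units)
    vals = vals.iloc[order]
    x = NeutroArray(vals["x_lower"].to_numpy(), vals["x_upper"].to_numpy(), strict=strict)
    y = NeutroArray(vals["y_lower"].to_numpy(), vals["y_upper"].to_numpy(), strict=strict)
    return NeutroPopulation(x, y, len(df), name=path.stem)


def write_neutro_csv(pop: NeutroPopulation, path) -> None:
    """Write a population losslessly (17 significant digits, LF endings)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "unit": np.arange(1, pop.N + 1),
            "x_lower": pop.x.lower,
            "x_upper": pop.x.upper,
            "y_lower": pop.y.lower,
            "y_upper": pop.y.upper,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")
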