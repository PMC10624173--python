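"""Point soil-survey tables: one row per sampling point.

A :class:`SampleTable` wraps a pandas DataFrame with an ``id`` column, planar
metre coordinates ``x``/``y`` (UTM-style; no geodesy anywhere in the
package), and one numeric column per measured soil parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SampleTable", "COORD_COLUMNS"]

COORD_COLUMNS = ("id", "x", "y")


@dataclass(frozen=True)
class SampleTable:
    """Point records (id, x, y, parameter values) for a soil survey."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COORD_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing required columns: {missing}")
        for c in ("x", "y"):
            if not np.issubdtype(df[c].dtype, np.number):
                raise ValueError(f"coordinate column {c!r} is not numeric")
            if df[c].isna().any():
                raise ValueError(f"coordinate column {c!r} contains missing values")

    @property
    def parameters(self) -> tuple[str, ...]:
        """Names of the measured-parameter columns (everything but id/x/y)."""
        return tuple(c for c in self.data.columns if c not in COORD_COLUMNS)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        """``(n, 2)`` array of x, y coordinates in metres."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def values(self, parameter: str) -> np.ndarray:
        if parameter not in self.parameters:
            raise KeyError(
                f"parameter {parameter!r} not in sample table "
                f"(has {list(self.parameters)})"
            )
        return self.data[parameter].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "SampleTable":
        return SampleTable(self.data.loc[mask].reset_index(drop=True))
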