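"""Yield-based validation of the soil-quality index.

Agreement between the index and observed crop yields (kg ha-1) is
quantified by ordinary least squares of yield on SQI and the coefficient of
determination R^2 = 1 - SS_res / SS_tot.  For a simple OLS fit this equals
the squared Pearson correlation of the two variables, so the report prints
both the regression R^2 and the raw correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["YieldRecord", "ValidationReport", "fit_line", "r_squared", "validate"]


@dataclass(frozen=True)
class YieldRecord:
    """One validation point: observed yield (kg ha-1) against its SQI."""

    point_id: object
    yield_kg_ha: float
    sqi: float

    def __post_init__(self) -> None:
        if not self.yield_kg_ha > 0:
            raise ValueError(f"yield must be positive, got {self.yield_kg_ha!r}")


@dataclass(frozen=True)
class ValidationReport:
    slope: float
    intercept: float
    r2: float
    pearson_r: float
    n: int

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "r2": self.r2,
                "pearson_r": self.pearson_r,
                "n": self.n,
            }
        )


def fit_line(x, y) -> tuple[float, float]:
    """Ordinary least squares line y = a + b x; returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (conventional form)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) != len(pred) or len(obs) < 2:
        raise ValueError("need >= 2 paired values")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def validate(records) -> ValidationReport:
    """Regress observed yield on SQI and report slope, intercept, R^2, n.

    ``records`` is an iterable of :class:`YieldRecord` or a DataFrame with
    ``yield_kg_ha`` and ``sqi`` columns.
    """
    if isinstance(records, pd.DataFrame):
        y = records["yield_kg_ha"].to_numpy(dtype=float)
        x = records["sqi"].to_numpy(dtype=float)
        n = len(records)
    else:
        records = list(records)
        y = np.array([r.yield_kg_ha for r in records])
        x = np.array([r.sqi for r in records])
        n = len(records)
    if n < 3:
        raise ValueError(f"validation needs >= 3 records, got {n}")
    slope, intercept = fit_line(x, y)
    pred = intercept + slope * x
    r2 = r_squared(y, pred)
    r = float(np.corrcoef(x, y)[0, 1])
    return ValidationReport(slope=slope, intercept=intercept, r2=r2,
                            pearson_r=r, n=n)
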