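"""Standard scoring functions (SSF) and the indicator threshold catalog.

Each soil parameter is mapped to a dimensionless suitability score in
[0.1, 1] by a piecewise-linear standard scoring function between a lower
threshold L and an upper threshold U:

* "more is better" (positive SSF): 0.1 below L, linear ramp
  ``0.1 + 0.9 (x - L)/(U - L)`` between, 1 above U — used for depth, AWC,
  HC, clay, CEC, OM and the fertility nutrients;
* "less is better" (negative SSF): the mirror image, 1 below L and 0.1
  above U — used for slope, BD, sand, silt, pH, EC, CaCO3, Na and ESP.

Both branches meet at 0.55 at the midpoint and satisfy
``positive(x) + negative(x) = 1.1`` for every x.

The built-in catalog covers the 24 wheat-barley indicators.  Where the
agronomic literature gives numeric suitability-class edges, L and U are the
worst-class and best-class edges; for the remaining parameters (texture
fractions, bulk density, micronutrients) L/U default to the 5th/95th
percentiles of the supplied survey, falling back to the descriptive min/max
of the reference survey when no data are given.  The catalog records which
rule produced each pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .samples import SampleTable

__all__ = [
    "IndicatorSpec",
    "ScoreTable",
    "SCORE_FLOOR",
    "ssf_more_is_better",
    "ssf_less_is_better",
    "default_catalog",
    "load_threshold_catalog",
    "save_threshold_catalog",
    "catalog_to_frame",
    "score_samples",
]

SCORE_FLOOR = 0.1

MORE_IS_BETTER = "more_is_better"
LESS_IS_BETTER = "less_is_better"


@dataclass(frozen=True)
class IndicatorSpec:
    """Scoring rule for one soil parameter.

    ``class_breaks`` optionally stores the suitability-class edges
    (S1|S2, S2|S3, S3|N1, N1|N2) in parameter units, ordered from the
    best-class edge to the worst.
    """

    name: str
    direction: str
    lower: float
    upper: float
    units: str = ""
    class_breaks: tuple[float, ...] | None = None
    source_rule: str = "table_edges"

    def __post_init__(self) -> None:
        if self.direction not in (MORE_IS_BETTER, LESS_IS_BETTER):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.lower < self.upper:
            raise ValueError(
                f"{self.name}: lower threshold {self.lower} must be < upper "
                f"{self.upper}"
            )

    def score(self, x) -> np.ndarray | float:
        if self.direction == MORE_IS_BETTER:
            return ssf_more_is_better(x, self.lower, self.upper)
        return ssf_less_is_better(x, self.lower, self.upper)


@dataclass(frozen=True)
class ScoreTable:
    """Per-point suitability scores, one column per indicator.

    ``data`` holds the point ``id`` column plus one score column per
    indicator; scores are in [0.1, 1] or NaN where the measurement was
    missing.  ``provenance`` names the catalog that produced the scores.
    """

    data: pd.DataFrame
    provenance: str = "default"

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c != "id")

    def values(self) -> pd.DataFrame:
        return self.data[list(self.parameters)]


def _check_finite(x: np.ndarray) -> None:
    if np.any(np.isinf(x)):
        raise ValueError("SSF input contains non-finite values")


def ssf_more_is_better(x, L: float, U: float):
    """Positive SSF: 0.1 at/below L, 1 at/above U, linear between."""
    if not L < U:
        raise ValueError(f"need L < U, got L={L}, U={U}")
    arr = np.asarray(x, dtype=float)
    _check_finite(arr)
    score = SCORE_FLOOR + (1.0 - SCORE_FLOOR) * (arr - L) / (U - L)
    out = np.clip(score, SCORE_FLOOR, 1.0)
    out = np.where(np.isnan(arr), np.nan, out)
    return float(out) if np.isscalar(x) else out


def ssf_less_is_better(x, L: float, U: float):
    """Negative SSF: 1 at/below L, 0.1 at/above U, linear between."""
    if not L < U:
        raise ValueError(f"need L < U, got L={L}, U={U}")
    arr = np.asarray(x, dtype=float)
    _check_finite(arr)
    score = 1.0 - (1.0 - SCORE_FLOOR) * (arr - L) / (U - L)
    out = np.clip(score, SCORE_FLOOR, 1.0)
    out = np.where(np.isnan(arr), np.nan, out)
    return float(out) if np.isscalar(x) else out


# ---------------------------------------------------------------------------
# Default wheat-barley catalog
#
# (direction, L, U, units, class_breaks) for parameters whose suitability
# class edges are numeric.  The total-N class edges as printed mix two
# decimal scales; they are used decimal-corrected (0.32/0.17/0.09/0.045 %),
# consistent with observed total-N ranges in the reference survey.

_TABLE_EDGE_SPECS: dict[str, tuple[str, float, float, str, tuple[float, ...]]] = {
    "Depth": (MORE_IS_BETTER, 20.0, 120.0, "cm", (120.0, 90.0, 50.0, 20.0)),
    "Slope": (LESS_IS_BETTER, 0.0, 30.0, "%", (6.0, 12.0, 20.0, 30.0)),
    "AWC": (MORE_IS_BETTER, 15.0, 50.0, "%", (50.0, 20.0, 15.0)),
    "HC": (MORE_IS_BETTER, 0.5, 6.25, "cm h-1", (6.25, 2.0, 0.5)),
    "pH": (LESS_IS_BETTER, 7.0, 8.5, "", (7.0, 7.8, 8.5)),
    "EC": (LESS_IS_BETTER, 4.0, 12.0, "dS m-1", (4.0, 6.0, 8.0, 12.0)),
    "CaCO3": (LESS_IS_BETTER, 30.0, 60.0, "%", (30.0, 40.0, 50.0, 60.0)),
    "OM": (MORE_IS_BETTER, 0.5, 2.0, "%", (2.0, 1.0, 0.5)),
    "CEC": (MORE_IS_BETTER, 8.0, 16.0, "cmol kg-1", (16.0, 8.0)),
    "ESP": (LESS_IS_BETTER, 10.0, 20.0, "%", (10.0, 15.0, 20.0)),
    "N": (MORE_IS_BETTER, 0.045, 0.32, "%", (0.32, 0.17, 0.09, 0.045)),
    "P": (MORE_IS_BETTER, 2.5, 80.0, "mg kg-1", (80.0, 25.0, 8.0, 2.5)),
    "K": (MORE_IS_BETTER, 0.13, 2.56, "cmol kg-1", (2.56, 0.74, 0.28, 0.13)),
    "Ca": (MORE_IS_BETTER, 1.19, 50.0, "cmol kg-1", (50.0, 17.5, 5.75, 1.19)),
    "Mg": (MORE_IS_BETTER, 0.42, 12.5, "cmol kg-1", (12.5, 4.0, 1.33, 0.42)),
    "Na": (LESS_IS_BETTER, 0.20, 2.0, "cmol kg-1", (0.20, 0.30, 0.70, 2.0)),
}

# direction and units for parameters scored on observed percentiles
_PERCENTILE_SPECS: dict[str, tuple[str, str]] = {
    "Clay": (MORE_IS_BETTER, "%"),
    "Silt": (LESS_IS_BETTER, "%"),
    "Sand": (LESS_IS_BETTER, "%"),
    "BD": (LESS_IS_BETTER, "g cm-3"),
    "Fe": (MORE_IS_BETTER, "mg kg-1"),
    "Cu": (MORE_IS_BETTER, "mg kg-1"),
    "Zn": (MORE_IS_BETTER, "mg kg-1"),
    "Mn": (MORE_IS_BETTER, "mg kg-1"),
}

PARAMETER_ORDER = (
    "Clay", "Silt", "Sand", "HC", "BD", "AWC", "Slope", "Depth",
    "pH", "EC", "OM", "CaCO3", "CEC", "ESP",
    "N", "P", "Ca", "Mg", "K", "Na", "Fe", "Zn", "Cu", "Mn",
)


def default_catalog(samples: SampleTable | None = None) -> list[IndicatorSpec]:
    """The built-in 24-parameter wheat-barley threshold catalog.

    Parameters without numeric class edges take L/U from the 5th/95th
    percentiles of ``samples`` when given, else from the reference survey's
    descriptive min/max.
    """
    from .synthetic import default_marginals  # late import: synthetic uses raster only

    marginals = {m.name: m for m in default_marginals()}
    catalog: list[IndicatorSpec] = []
    for name in PARAMETER_ORDER:
        if name in _TABLE_EDGE_SPECS:
            direction, lo, up, units, breaks = _TABLE_EDGE_SPECS[name]
            catalog.append(
                IndicatorSpec(name, direction, lo, up, units,
                              class_breaks=breaks, source_rule="table_edges")
            )
        else:
            direction, units = _PERCENTILE_SPECS[name]
            if samples is not None and name in samples.parameters:
                vals = samples.values(name)
                vals = vals[np.isfinite(vals)]
                lo, up = np.percentile(vals, [5.0, 95.0])
                rule = "percentile_5_95"
            else:
                m = marginals[name]
                lo, up = m.vmin, m.vmax
                rule = "marginal_min_max"
            if not lo < up:
                raise ValueError(f"{name}: degenerate percentile thresholds {lo}/{up}")
            catalog.append(
                IndicatorSpec(name, direction, float(lo), float(up), units,
                              source_rule=rule)
            )
    return catalog


# ---------------------------------------------------------------------------
# Catalog I/O


def load_threshold_catalog(source: str | Path | dict) -> list[IndicatorSpec]:
    """Load a threshold catalog from a YAML file or an equivalent mapping.

    Layout: one key per parameter with ``direction``, ``lower``, ``upper``
    and optional ``units``, ``class_breaks``, ``source_rule``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = source
    if not raw:
        raise ValueError("empty threshold catalog")
    catalog = []
    for name, entry in raw.items():
        try:
            catalog.append(
                IndicatorSpec(
                    name=str(name),
                    direction=entry["direction"],
                    lower=float(entry["lower"]),
                    upper=float(entry["upper"]),
                    units=str(entry.get("units", "")),
                    class_breaks=(
                        tuple(float(b) for b in entry["class_breaks"])
                        if entry.get("class_breaks") else None
                    ),
                    source_rule=str(entry.get("source_rule", "user")),
                )
            )
        except KeyError as exc:
            raise ValueError(f"catalog entry {name!r} missing field {exc}") from exc
    return catalog


def save_threshold_catalog(catalog: Sequence[IndicatorSpec], path: str | Path) -> Path:
    """Write a catalog to YAML; re-loading reproduces it exactly."""
    out = {}
    for spec in catalog:
        entry = {
            "direction": spec.direction,
            "lower": spec.lower,
            "upper": spec.upper,
            "units": spec.units,
            "source_rule": spec.source_rule,
        }
        if spec.class_breaks is not None:
            entry["class_breaks"] = list(spec.class_breaks)
        out[spec.name] = entry
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
    return path


def catalog_to_frame(catalog: Sequence[IndicatorSpec]) -> pd.DataFrame:
    """Tabular view of the catalog (one row per parameter)."""
    return pd.DataFrame(
        {
            "parameter": [s.name for s in catalog],
            "direction": [s.direction for s in catalog],
            "lower": [s.lower for s in catalog],
            "upper": [s.upper for s in catalog],
            "units": [s.units for s in catalog],
            "source_rule": [s.source_rule for s in catalog],
            "class_breaks": [
                "/".join(str(b) for b in s.class_breaks) if s.class_breaks else ""
                for s in catalog
            ],
        }
    )


# ---------------------------------------------------------------------------


def score_samples(
    samples: SampleTable,
    catalog: Sequence[IndicatorSpec],
    provenance: str = "default",
) -> ScoreTable:
    """Apply the direction-appropriate SSF to every catalog parameter.

    Missing measurements propagate as NaN scores and trigger a warning;
    catalog parameters absent from the table are reported (and skipped).
    Raises if no catalog parameter overlaps the sample columns.
    """
    present = [s for s in catalog if s.name in samples.parameters]
    absent = [s.name for s in catalog if s.name not in samples.parameters]
    if not present:
        raise ValueError(
            "no overlap between catalog parameters and sample columns"
        )
    if absent:
        warnings.warn(
            f"catalog parameters missing from sample table: {absent}",
            stacklevel=2,
        )
    out = {"id": samples.data["id"].to_numpy()}
    n_missing = 0
    for spec in present:
        vals = samples.values(spec.name)
        n_missing += int(np.isnan(vals).sum())
        out[spec.name] = spec.score(vals)
    if n_missing:
        warnings.warn(
            f"{n_missing} missing measurements propagated as missing scores",
            stacklevel=2,
        )
    return ScoreTable(pd.DataFrame(out), provenance=provenance)
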