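"""Soil-quality index: weighted linear combination, classification, masking.

The soil-quality index of a point or cell is the weighted linear
combination SQI = sum_i W_i X_i of its indicator scores X_i in [0.1, 1]
under AHP weights W_i summing to 1, so SQI itself lies in [0.1, 1].  For
suitability classification the index is bridged to a 0-100 scale
(index100 = 100 x SQI) and cut into FAO-style classes:

    S1 very good [80, 100]   S2 good [60, 80)   S3 medium [50, 60)
    N1 weak [20, 50)         N2 bad  [0, 20)

The class intervals are half-open upward (S1 closed at 100), which makes
the classification exhaustive and non-overlapping.  Non-agricultural areas
(settlements, stream beds, ponds, canals) can be masked out of the class
raster by polygon, and class areas tabulated in hectares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .ahp import WeightVector
from .raster import RasterGrid
from .scoring import ScoreTable

__all__ = [
    "SuitabilityResult",
    "CLASS_BOUNDS",
    "CLASS_CODES",
    "MASK_CODE_BASE",
    "compute_sqi",
    "classify",
    "classify_raster",
    "mask_and_map",
    "tabulate_areas",
    "class_code_legend",
]

#: Lower index100 bound of each suitability class, best to worst.
CLASS_BOUNDS = (("S1", 80.0), ("S2", 60.0), ("S3", 50.0), ("N1", 20.0), ("N2", 0.0))

#: Integer raster codes for classes; mask categories start at MASK_CODE_BASE.
CLASS_CODES = {"S1": 1, "S2": 2, "S3": 3, "N1": 4, "N2": 5}
MASK_CODE_BASE = 10


@dataclass(frozen=True)
class SuitabilityResult:
    """Per-point SQI with class labels plus provenance of weights/catalog."""

    data: pd.DataFrame  # columns: id, sqi, index100, class_label
    weights_used: WeightVector
    catalog_used: str = "default"
    renormalized: bool = False


def compute_sqi(
    scores: ScoreTable,
    weights: WeightVector,
    renormalize: bool = False,
) -> SuitabilityResult:
    """Weighted linear combination of indicator scores, per point.

    Weight labels must be a subset of the score columns.  A point missing
    any weighted score gets a missing SQI, unless ``renormalize`` is set, in
    which case the weights of the available scores are rescaled to sum to 1
    (and the result records that this happened).
    """
    labels = [l for l in weights.labels if l in scores.parameters]
    if not labels:
        raise ValueError("no overlap between weight labels and score columns")
    missing_cols = [l for l in weights.labels if l not in scores.parameters]
    if missing_cols:
        raise ValueError(
            f"weighted parameters absent from the score table: {missing_cols}"
        )
    w = np.array([weights[l] for l in labels])
    x = scores.data[labels].to_numpy(dtype=float)
    have = np.isfinite(x)
    if renormalize:
        wsum = (have * w).sum(axis=1)
        with np.errstate(invalid="ignore"):
            sqi = np.nansum(x * w, axis=1) / wsum
        sqi = np.where(wsum > 0, sqi, np.nan)
        renorm = bool((~have).any())
    else:
        sqi = x @ w
        renorm = False
        n_dropped = int((~have.all(axis=1)).sum())
        if n_dropped:
            warnings.warn(
                f"{n_dropped} points have missing scores and get missing SQI "
                "(set renormalize=True to rescale remaining weights)",
                stacklevel=2,
            )
    df = pd.DataFrame(
        {
            "id": scores.data["id"].to_numpy(),
            "sqi": sqi,
            "index100": 100.0 * sqi,
        }
    )
    df["class_label"] = [
        classify(v) if np.isfinite(v) else "missing" for v in df["index100"]
    ]
    return SuitabilityResult(
        df, weights_used=weights, catalog_used=scores.provenance,
        renormalized=renorm,
    )


def classify(index100: float) -> str:
    """Suitability class of a 0-100 index value (half-open upward intervals)."""
    if not np.isfinite(index100) or index100 < 0.0 or index100 > 100.0:
        raise ValueError(f"index must be in [0, 100], got {index100!r}")
    for label, lower in CLASS_BOUNDS:
        if index100 >= lower:
            return label
    return "N2"  # unreachable: N2 lower bound is 0


def classify_raster(sqi_raster: RasterGrid) -> RasterGrid:
    """Class-coded raster (integer codes) from a [0.1, 1] SQI raster."""
    vals = sqi_raster.values
    ok = sqi_raster.mask()
    idx = 100.0 * vals
    if np.any(ok & ((idx < -1e-9) | (idx > 100.0 + 1e-9))):
        raise ValueError("SQI raster holds values outside [0, 1]")
    codes = np.full(vals.shape, int(sqi_raster.nodata), dtype=float)
    codes[ok] = CLASS_CODES["N2"]
    for label, lower in reversed(CLASS_BOUNDS[:-1]):  # N1 up to S1
        codes[ok & (idx >= lower)] = CLASS_CODES[label]
    return sqi_raster.with_values(codes)


def mask_and_map(
    sqi_raster: RasterGrid,
    masks: Sequence[tuple[str, "shapely.Geometry"]] = (),
) -> tuple[RasterGrid, dict[int, str]]:
    """Classify an SQI raster and overlay mask polygons.

    ``masks`` is a sequence of (category, polygon) pairs in the raster's
    coordinate frame; cells whose centre falls inside any polygon get that
    category's code (10, 11, ... in order of first appearance), all other
    data cells get their suitability-class code.  Returns the class raster
    and the code legend {code: label}.
    """
    classed = classify_raster(sqi_raster)
    legend = {v: k for k, v in CLASS_CODES.items()}
    if not masks:
        return classed, legend
    gx, gy = sqi_raster.cell_centers()
    xmin, ymin, xmax, ymax = sqi_raster.extent
    values = classed.values.copy()
    category_codes: dict[str, int] = {}
    for category, geom in masks:
        gxmin, gymin, gxmax, gymax = shapely.bounds(geom)
        if gxmax < xmin or gxmin > xmax or gymax < ymin or gymin > ymax:
            raise ValueError(
                f"mask {category!r} lies entirely outside the raster extent; "
                "is it in a different coordinate frame? (no reprojection is "
                "attempted)"
            )
        if category not in category_codes:
            category_codes[category] = MASK_CODE_BASE + len(category_codes)
            legend[category_codes[category]] = category
        inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(
            values.shape
        )
        values[inside & classed.mask()] = category_codes[category]
    return classed.with_values(values), legend


def tabulate_areas(
    class_raster: RasterGrid, legend: Mapping[int, str] | None = None
) -> pd.DataFrame:
    """Area (ha) and share (%) per class code over the non-no-data cells.

    Cell area is ``cellsize**2`` m2, converted to hectares; shares are over
    classified + masked cells and sum to 100.
    """
    if legend is None:
        legend = {v: k for k, v in CLASS_CODES.items()}
    ok = class_raster.mask()
    codes = class_raster.values[ok].astype(int)
    if codes.size == 0:
        raise ValueError("no classified cells to tabulate")
    cell_ha = class_raster.cellsize**2 / 10_000.0
    uniq, counts = np.unique(codes, return_counts=True)
    rows = []
    total = counts.sum() * cell_ha
    for code, cnt in zip(uniq, counts):
        rows.append(
            {
                "class": legend.get(int(code), str(int(code))),
                "code": int(code),
                "area_ha": cnt * cell_ha,
                "share_pct": 100.0 * cnt * cell_ha / total,
            }
        )
    df = pd.DataFrame(rows).sort_values("code").reset_index(drop=True)
    df.attrs["total_area_ha"] = total
    return df


def class_code_legend(legend: Mapping[int, str]) -> str:
    """Sidecar text describing the integer class codes of a raster."""
    lines = ["code\tlabel"]
    for code in sorted(legend):
        lines.append(f"{code}\t{legend[code]}")
    return "\n".join(lines) + "\n"
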