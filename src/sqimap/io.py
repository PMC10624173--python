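"""Readers, writers, run configuration and the end-to-end pipeline.

The pipeline ties the stages together in the survey-to-map order:
score the sampled parameters, weight them by AHP, interpolate, combine
into the soil-quality index, classify, mask, tabulate areas and (when
yields are supplied or simulated) validate against yields.  Every run
writes CSV reports, ESRI ASCII rasters and a JSON manifest recording the
seed and the method choices taken, which suffices to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _geojson_shape

from . import ahp, interpolation, scoring, sqi as sqi_mod, synthetic, validation
from .raster import RasterGrid
from .samples import SampleTable

__all__ = [
    "read_samples",
    "read_yields",
    "read_masks_geojson",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "spec_from_label",
]

log = logging.getLogger(__name__)

KNOWN_PARAMETERS = set(scoring.PARAMETER_ORDER)


def read_samples(path: str | Path, decimal: str = "auto") -> SampleTable:
    """Read a point-survey CSV (id, x, y, parameter columns).

    ``decimal="auto"`` retries with a decimal comma when plain parsing
    leaves numeric-looking columns as text (survey exports from comma-locale
    spreadsheets).  Unknown parameter columns are kept but flagged.
    """
    path = Path(path)

    def _read(dec: str) -> pd.DataFrame:
        return pd.read_csv(path, decimal=dec)

    df = _read("." if decimal == "auto" else decimal)
    if decimal == "auto":
        object_cols = [
            c for c in df.columns if c not in ("id",) and df[c].dtype == object
        ]
        if object_cols:
            df = _read(",")
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(1, len(df) + 1))
    for coord in ("x", "y"):
        if coord not in df.columns:
            raise ValueError(f"{path}: missing coordinate column {coord!r}")
    for col in df.columns:
        if col == "id":
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()
                     & df[col].notna()].index
            row = int(bad[0]) if len(bad) else -1
            raise ValueError(
                f"{path}: unparseable numeric cell in column {col!r}, row {row}"
            ) from exc
    unknown = [
        c for c in df.columns
        if c not in ("id", "x", "y") and c not in KNOWN_PARAMETERS
    ]
    if unknown:
        warnings.warn(f"{path}: unknown parameter columns kept: {unknown}",
                      stacklevel=2)
    return SampleTable(df)


def read_yields(
    path: str | Path,
    points: pd.DataFrame | None = None,
    tolerance: float = 1.0,
) -> pd.DataFrame:
    """Read an observed-yield CSV (id, yield_kg_ha, optional x/y).

    With coordinates present and ``points`` given (a frame holding id/x/y),
    records are joined to the nearest point within ``tolerance`` metres;
    otherwise they join by id.
    """
    df = pd.read_csv(path)
    if "yield_kg_ha" not in df.columns:
        raise ValueError(f"{path}: missing yield_kg_ha column")
    if points is not None and {"x", "y"}.issubset(df.columns):
        from scipy.spatial import cKDTree

        tree = cKDTree(points[["x", "y"]].to_numpy(dtype=float))
        dist, idx = tree.query(df[["x", "y"]].to_numpy(dtype=float))
        keep = dist <= tolerance
        if not keep.all():
            warnings.warn(
                f"{path}: {int((~keep).sum())} yield records farther than "
                f"{tolerance} m from any point were dropped",
                stacklevel=2,
            )
        df = df.loc[keep].copy()
        df["id"] = points["id"].to_numpy()[idx[keep]]
    return df


def read_masks_geojson(path: str | Path) -> list[tuple[str, shapely.Geometry]]:
    """Read mask polygons from GeoJSON; category from the ``category`` (or
    ``name``) property, default ``mask``."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features", [gj] if gj.get("type") != "FeatureCollection" else [])
    out = []
    for feat in feats:
        props = feat.get("properties") or {}
        category = str(props.get("category", props.get("name", "mask")))
        out.append((category, _geojson_shape(feat["geometry"])))
    if not out:
        raise ValueError(f"{path}: no mask features found")
    return out


def spec_from_label(label: str) -> interpolation.InterpolatorSpec:
    """Parse an interpolator label like ``IDW-power2`` or ``Kriging-ordinary_exponential``."""
    family, _, variant = label.partition("-")
    return interpolation.InterpolatorSpec(family, variant)


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class RunConfig:
    """Everything a pipeline run needs; all paths optional (synthetic run)."""

    samples_path: str | None = None
    catalog_path: str | None = None
    matrix_paths: dict[str, str] = field(default_factory=dict)
    masks_path: str | None = None
    yields_path: str | None = None
    weight_method: str = "eigenvector"
    strict_consistency: bool = True
    candidates: tuple[str, ...] = ("IDW-power1", "IDW-power2", "IDW-power3",
                                   "RBF-TPS", "RBF-CRS", "RBF-ST")
    cellsize: float = 90.0
    sqi_order: str = "interpolate_then_score"
    simulate_yields: bool = False
    seed: int = 0
    outdir: str = "sqimap_run"
    # synthetic-survey settings, used when samples_path is None
    extent: tuple[float, float] = (6480.0, 6480.0)
    spacing: float = 400.0

    def validate(self) -> None:
        for p in (self.samples_path, self.catalog_path, self.masks_path,
                  self.yields_path, *self.matrix_paths.values()):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.sqi_order not in ("interpolate_then_score", "score_then_interpolate"):
            raise ValueError(f"unknown sqi_order {self.sqi_order!r}")
        for label in self.candidates:
            spec_from_label(label)


@dataclass
class PipelineResult:
    samples: SampleTable
    weights: ahp.WeightVector
    consistency: dict[str, ahp.ConsistencyReport]
    sqi_raster: RasterGrid
    class_raster: RasterGrid
    legend: dict[int, str]
    areas: pd.DataFrame
    point_result: sqi_mod.SuitabilityResult
    leaderboard: pd.DataFrame
    validation_report: validation.ValidationReport | None
    manifest: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full suitability workflow and write all reports."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [],
                      "config": {k: v for k, v in dataclasses.asdict(config).items()}}

    def _stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        _stage("samples")
        if config.samples_path:
            samples = read_samples(config.samples_path)
        else:
            fspec = synthetic.FieldSpec(
                extent=config.extent, cellsize=config.cellsize, seed=config.seed
            )
            _, samples, survey_manifest = synthetic.generate_survey(
                fspec, spacing=config.spacing
            )
            manifest["synthetic_survey"] = survey_manifest
            samples.data.to_csv(outdir / "samples.csv", index=False)
    except Exception as exc:
        raise StageError("samples", exc) from exc

    try:
        _stage("weights")
        if config.matrix_paths:
            mats = {
                level: ahp.read_pairwise_csv(path, level=level)
                for level, path in config.matrix_paths.items()
            }
            main_w = ahp.derive_weights(mats["main"], config.weight_method)
            groups = {
                lvl: ahp.derive_weights(m, config.weight_method)
                for lvl, m in mats.items() if lvl != "main"
            }
            weights = ahp.global_weights(main_w, groups)
            reports = {
                lvl: ahp.consistency(m, ahp.derive_weights(m, config.weight_method))
                for lvl, m in mats.items()
            }
        else:
            weights, reports = ahp.default_hierarchy_weights(config.weight_method)
        bad = [lvl for lvl, r in reports.items() if not r.acceptable]
        if bad and config.strict_consistency:
            raise ValueError(
                f"pairwise matrices exceed CR 0.10: {bad}; revise the judgements"
            )
        manifest["weight_method"] = config.weight_method
        ahp.consistency_table(list(reports.values())).to_csv(
            outdir / "consistency.csv"
        )
        weights.as_series().rename_axis("parameter").to_csv(
            outdir / "weights.csv", header=["weight"]
        )
    except Exception as exc:
        raise StageError("weights", exc) from exc

    try:
        _stage("scoring")
        if config.catalog_path:
            catalog = scoring.load_threshold_catalog(config.catalog_path)
            manifest["threshold_rule"] = "user_catalog"
        else:
            catalog = scoring.default_catalog(samples)
            manifest["threshold_rule"] = "table_edges+percentiles"
        scoring.catalog_to_frame(catalog).to_csv(outdir / "catalog.csv", index=False)
        scores = scoring.score_samples(samples, catalog)
        point_result = sqi_mod.compute_sqi(scores, weights)
        point_result.data.to_csv(outdir / "sqi_points.csv", index=False)
    except Exception as exc:
        raise StageError("scoring", exc) from exc

    try:
        _stage("interpolation")
        candidates = [spec_from_label(l) for l in config.candidates]
        xs, ys = samples.coords[:, 0], samples.coords[:, 1]
        extent = (xs.min(), ys.min(), xs.max(), ys.max())
        boards: dict[str, list[interpolation.CVResult]] = {}
        manifest["sqi_order"] = config.sqi_order
        if config.sqi_order == "interpolate_then_score":
            param_rasters: dict[str, RasterGrid] = {}
            for spec in catalog:
                if spec.name not in samples.parameters:
                    continue
                if len(candidates) > 1:
                    best, results = interpolation.select_best(
                        samples, spec.name, candidates
                    )
                    boards[spec.name] = results
                else:
                    best = candidates[0]
                param_rasters[spec.name] = interpolation.rasterize(
                    best, samples, spec.name, extent, config.cellsize
                )
            ref = next(iter(param_rasters.values()))
            acc = np.zeros_like(ref.values)
            ok = np.ones(ref.values.shape, dtype=bool)
            for spec in catalog:
                if spec.name not in param_rasters:
                    continue
                grid = param_rasters[spec.name]
                ok &= grid.mask()
                acc = acc + weights[spec.name] * np.asarray(
                    spec.score(np.where(grid.mask(), grid.values, np.nan))
                )
            sqi_values = np.where(ok, acc, ref.nodata)
            sqi_raster = ref.with_values(sqi_values)
        else:  # score_then_interpolate
            pts = samples.data[["id", "x", "y"]].copy()
            pts["SQI"] = point_result.data["sqi"].to_numpy()
            sqi_samples = SampleTable(pts.dropna(subset=["SQI"]))
            if len(candidates) > 1:
                best, results = interpolation.select_best(
                    sqi_samples, "SQI", candidates
                )
                boards["SQI"] = results
            else:
                best = candidates[0]
            sqi_raster = interpolation.rasterize(
                best, sqi_samples, "SQI", extent, config.cellsize
            )
            sqi_raster = sqi_raster.with_values(
                np.where(
                    sqi_raster.mask(),
                    np.clip(sqi_raster.values, 0.0, 1.0),
                    sqi_raster.nodata,
                )
            )
        board = interpolation.leaderboard(boards) if boards else pd.DataFrame()
        board.to_csv(outdir / "leaderboard.csv")
        sqi_raster.write_ascii(outdir / "sqi.asc")
    except Exception as exc:
        raise StageError("interpolation", exc) from exc

    try:
        _stage("classification")
        masks = read_masks_geojson(config.masks_path) if config.masks_path else []
        class_raster, legend = sqi_mod.mask_and_map(sqi_raster, masks)
        areas = sqi_mod.tabulate_areas(class_raster, legend)
        class_raster.write_ascii(outdir / "classes.asc")
        (outdir / "classes.legend.txt").write_text(
            sqi_mod.class_code_legend(legend)
        )
        areas.to_csv(outdir / "areas.csv", index=False)
    except Exception as exc:
        raise StageError("classification", exc) from exc

    report = None
    try:
        _stage("validation")
        point_sqi = point_result.data.dropna(subset=["sqi"])
        if config.yields_path:
            ydf = read_yields(config.yields_path, samples.data)
            merged = ydf.merge(point_sqi[["id", "sqi"]], on="id")
            report = validation.validate(merged)
        elif config.simulate_yields:
            y = synthetic.simulate_yield(
                point_sqi["sqi"].to_numpy(), seed=config.seed
            )
            frame = pd.DataFrame(
                {"id": point_sqi["id"], "yield_kg_ha": y,
                 "sqi": point_sqi["sqi"]}
            )
            frame.to_csv(outdir / "yields.csv", index=False)
            report = validation.validate(frame)
        if report is not None:
            report.as_series().to_csv(outdir / "validation.csv", header=["value"])
            manifest["validation_r2"] = report.r2
    except Exception as exc:
        raise StageError("validation", exc) from exc

    manifest["areas"] = areas.to_dict(orient="records")
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return PipelineResult(
        samples=samples, weights=weights,
        consistency=reports, sqi_raster=sqi_raster,
        class_raster=class_raster, legend=legend, areas=areas,
        point_result=point_result, leaderboard=board,
        validation_report=report, manifest=manifest,
    )
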