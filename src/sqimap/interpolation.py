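"""Spatial interpolation of point surveys and RMSE-based model selection.

Fifteen candidate interpolators are compared per parameter by leave-one-out
cross-validated RMSE, and the minimiser wins:

* inverse distance weighting with powers 1, 2, 3 (global neighbourhood);
* radial-basis splines: thin-plate (TPS), completely regularized (CRS) and
  spline with tension (ST), in their standard GIS formulations;
* kriging: ordinary, simple and universal, each with a gaussian, spherical
  or exponential semivariogram fitted to the empirical variogram by
  weighted least squares.

All distances are Euclidean on projected metre coordinates.  Ties in the
selection are broken by the fixed enumeration order above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist
from scipy.special import k0
import shapely

from .raster import RasterGrid
from .samples import SampleTable

__all__ = [
    "InterpolatorSpec",
    "CVResult",
    "Variogram",
    "InterpolationError",
    "candidate_specs",
    "predict",
    "fit_interpolator",
    "loocv_rmse",
    "select_best",
    "rasterize",
    "leaderboard",
    "fit_variogram",
]

_COINCIDENT_TOL = 1e-9  # metres
_EULER_GAMMA = 0.5772156649015329


class InterpolationError(RuntimeError):
    pass


@dataclass(frozen=True)
class InterpolatorSpec:
    """One of the 15 candidate interpolators.

    family/variant pairs: ``IDW`` with ``power1|power2|power3``; ``RBF``
    with ``TPS|CRS|ST``; ``Kriging`` with
    ``ordinary|simple|universal`` ``_`` ``gaussian|spherical|exponential``.
    ``params`` holds variant-specific settings (RBF kernel width, variogram
    overrides, simple-kriging mean).
    """

    family: str
    variant: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = {
            "IDW": {"power1", "power2", "power3"},
            "RBF": {"TPS", "CRS", "ST"},
            "Kriging": {
                f"{k}_{m}"
                for k in ("ordinary", "simple", "universal")
                for m in ("gaussian", "spherical", "exponential")
            },
        }
        if self.family not in valid or self.variant not in valid[self.family]:
            raise ValueError(
                f"unknown interpolator ({self.family!r}, {self.variant!r})"
            )

    @property
    def label(self) -> str:
        return f"{self.family}-{self.variant}"


def candidate_specs() -> list[InterpolatorSpec]:
    """The 15 candidates in their fixed (tie-breaking) enumeration order."""
    out = [InterpolatorSpec("IDW", f"power{p}") for p in (1, 2, 3)]
    out += [InterpolatorSpec("RBF", v) for v in ("TPS", "CRS", "ST")]
    for krig in ("ordinary", "simple", "universal"):
        for model in ("gaussian", "spherical", "exponential"):
            out.append(InterpolatorSpec("Kriging", f"{krig}_{model}"))
    return out


@dataclass(frozen=True)
class CVResult:
    """Leave-one-out cross-validation outcome for one interpolator."""

    spec: InterpolatorSpec
    rmse: float
    n: int
    residuals: np.ndarray
    valid: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# Variogram


@dataclass(frozen=True)
class Variogram:
    """Semivariogram model gamma(h) = nugget + psill * g(h; range).

    ``model`` is gaussian, spherical or exponential; ``range_`` is the
    practical range in metres (gaussian/exponential reach ~95% of the sill
    there; spherical reaches it exactly).
    """

    model: str
    nugget: float
    psill: float
    range_: float

    def structure(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        a = self.range_
        if self.model == "exponential":
            return 1.0 - np.exp(-3.0 * h / a)
        if self.model == "gaussian":
            return 1.0 - np.exp(-3.0 * (h / a) ** 2)
        if self.model == "spherical":
            hr = np.clip(h / a, 0.0, 1.0)
            return 1.5 * hr - 0.5 * hr**3
        raise ValueError(f"unknown variogram model {self.model!r}")

    def gamma(self, h: np.ndarray) -> np.ndarray:
        return self.nugget + self.psill * self.structure(h)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """C(h) with C(0) = nugget + psill (exact interpolation at lag 0)."""
        h = np.asarray(h, dtype=float)
        c = self.psill * (1.0 - self.structure(h))
        return np.where(h < _COINCIDENT_TOL, self.nugget + self.psill, c)


def fit_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    model: str,
    n_bins: int = 12,
) -> Variogram:
    """Fit a semivariogram model to the empirical variogram.

    Empirical semivariances on ``n_bins`` equal-width distance bins up to
    half the maximum pairwise distance, fitted by least squares weighted by
    pair counts; nugget floored at 0.
    """
    d = cdist(coords, coords)
    iu = np.triu_indices_from(d, k=1)
    h = d[iu]
    sq = 0.5 * (values[:, None] - values[None, :]) ** 2
    g = sq[iu]
    hmax = h.max() / 2.0
    if hmax <= 0:
        raise InterpolationError("all points coincide; cannot fit a variogram")
    edges = np.linspace(0.0, hmax, n_bins + 1)
    keep = h <= hmax
    idx = np.clip(np.digitize(h[keep], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore"):
        gamma_emp = np.bincount(idx, weights=g[keep], minlength=n_bins) / counts
        h_mid = np.bincount(idx, weights=h[keep], minlength=n_bins) / counts
    ok = counts > 0
    h_mid, gamma_emp, counts = h_mid[ok], gamma_emp[ok], counts[ok]
    var = float(np.var(values))
    if var < 1e-15 or len(h_mid) < 3:
        return Variogram(model, 0.0, max(var, 1e-12), max(hmax, 1.0))

    def resid(p):
        nugget, psill, rng = p
        vg = Variogram(model, nugget, psill, rng)
        return np.sqrt(counts) * (vg.gamma(h_mid) - gamma_emp)

    x0 = np.array([0.0, var, hmax / 2.0])
    bounds = ([0.0, 1e-12, hmax * 1e-3], [var * 2.0 + 1e-12, var * 4.0, hmax * 4.0])
    sol = least_squares(resid, x0, bounds=bounds)
    nugget, psill, rng = sol.x
    return Variogram(model, float(nugget), float(psill), float(rng))


# ---------------------------------------------------------------------------
# Fitted interpolators


def _duplicate_check(coords: np.ndarray) -> None:
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    if d[i, j] < _COINCIDENT_TOL:
        raise InterpolationError(
            f"duplicate sample locations at rows {min(i, j)} and {max(i, j)}; "
            "the linear system is singular"
        )


def _mean_nn_distance(coords: np.ndarray) -> float:
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


class _FittedBase:
    def __init__(self, coords: np.ndarray, values: np.ndarray):
        self.center = coords.mean(axis=0)
        self.coords = coords - self.center
        self.values = values

    def predict(self, query: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _FittedIDW(_FittedBase):
    def __init__(self, coords, values, power: int):
        super().__init__(coords, values)
        self.power = power

    def predict(self, query):
        d = cdist(np.asarray(query, dtype=float) - self.center, self.coords)
        out = np.empty(len(d))
        hit = d < _COINCIDENT_TOL
        exact = hit.any(axis=1)
        for i in np.where(exact)[0]:
            out[i] = self.values[np.argmax(hit[i])]
        rest = ~exact
        if rest.any():
            w = d[rest] ** (-float(self.power))
            out[rest] = (w * self.values).sum(axis=1) / w.sum(axis=1)
        return out


def _rbf_kernel(r: np.ndarray, kind: str, width: float) -> np.ndarray:
    """Radial kernels: TPS r^2 log r; CRS and ST in their standard GIS forms
    (completely regularized spline and spline with tension), both 0 at r=0."""
    r = np.asarray(r, dtype=float)
    small = r < 1e-12
    rs = np.where(small, 1.0, r)
    if kind == "TPS":
        out = rs**2 * np.log(rs)
    elif kind == "CRS":
        tau = width
        out = (
            rs**2 / 4.0 * (np.log(rs / (2.0 * tau)) + _EULER_GAMMA - 1.0)
            + tau**2
            * (k0(rs / tau) + _EULER_GAMMA + np.log(rs / (2.0 * tau)))
        ) / (2.0 * np.pi)
    elif kind == "ST":
        phi = 1.0 / width
        out = -(np.log(rs * phi / 2.0) + _EULER_GAMMA + k0(rs * phi)) / (
            2.0 * np.pi * phi**2
        )
    else:
        raise ValueError(f"unknown RBF kernel {kind!r}")
    return np.where(small, 0.0, out)


class _FittedRBF(_FittedBase):
    def __init__(self, coords, values, kind: str, width: float | None):
        super().__init__(coords, values)
        _duplicate_check(coords)
        self.kind = kind
        self.width = width if width is not None else _mean_nn_distance(coords)
        n = len(coords)
        K = _rbf_kernel(cdist(self.coords, self.coords), kind, self.width)
        P = self._poly(self.coords)
        m = P.shape[1]
        A = np.zeros((n + m, n + m))
        A[:n, :n] = K
        A[:n, n:] = P
        A[n:, :n] = P.T
        rhs = np.concatenate([values, np.zeros(m)])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise InterpolationError(f"singular RBF system: {exc}") from exc
        self.w, self.a = sol[:n], sol[n:]

    def _poly(self, xy: np.ndarray) -> np.ndarray:
        # tension spline uses a constant trend; TPS/CRS a full linear one
        if self.kind == "ST":
            return np.ones((len(xy), 1))
        return np.column_stack([np.ones(len(xy)), xy])

    def predict(self, query):
        q = np.asarray(query, dtype=float) - self.center
        K = _rbf_kernel(cdist(q, self.coords), self.kind, self.width)
        return K @ self.w + self._poly(q) @ self.a


class _FittedKriging(_FittedBase):
    def __init__(self, coords, values, krig: str, variogram: Variogram,
                 mean: float | None = None):
        super().__init__(coords, values)
        _duplicate_check(coords)
        self.krig = krig
        self.vg = variogram
        self.mean = float(np.mean(values)) if mean is None else float(mean)
        n = len(coords)
        C = variogram.covariance(cdist(self.coords, self.coords))
        if krig == "simple":
            A = C
        elif krig == "ordinary":
            A = np.zeros((n + 1, n + 1))
            A[:n, :n] = C
            A[:n, n] = 1.0
            A[n, :n] = 1.0
        elif krig == "universal":
            F = np.column_stack([np.ones(n), self.coords])
            m = F.shape[1]
            A = np.zeros((n + m, n + m))
            A[:n, :n] = C
            A[:n, n:] = F
            A[n:, :n] = F.T
        else:
            raise ValueError(f"unknown kriging variant {krig!r}")
        try:
            self._lu = lu_factor(A)
        except np.linalg.LinAlgError as exc:
            raise InterpolationError(f"singular kriging system: {exc}") from exc
        self._n = n

    def predict(self, query):
        q = np.asarray(query, dtype=float) - self.center
        c = self.vg.covariance(cdist(self.coords, q))  # (n, nq)
        n = self._n
        if self.krig == "simple":
            rhs = c
            lam = lu_solve(self._lu, rhs)
            return self.mean + lam.T @ (self.values - self.mean)
        if self.krig == "ordinary":
            rhs = np.vstack([c, np.ones((1, len(q)))])
        else:  # universal
            fq = np.column_stack([np.ones(len(q)), q]).T
            rhs = np.vstack([c, fq])
        lam = lu_solve(self._lu, rhs)[:n]
        return lam.T @ self.values


def fit_interpolator(
    spec: InterpolatorSpec, points: SampleTable, parameter: str
):
    """Fit ``spec`` to the finite-valued samples of ``parameter``."""
    vals = points.values(parameter)
    ok = np.isfinite(vals)
    coords, vals = points.coords[ok], vals[ok]
    if len(vals) < 1:
        raise InterpolationError(f"no finite samples for {parameter!r}")
    if spec.family == "IDW":
        power = int(spec.variant[-1])
        return _FittedIDW(coords, vals, power)
    if spec.family == "RBF":
        return _FittedRBF(coords, vals, spec.variant, spec.params.get("width"))
    krig, model = spec.variant.split("_")
    if len(vals) < 10:
        raise InterpolationError(
            f"kriging needs >= 10 points to fit a variogram (got {len(vals)})"
        )
    vg = spec.params.get("variogram")
    if vg is None:
        vg = fit_variogram(coords, vals, model)
    if np.var(vals) < 1e-15:
        const = float(vals[0])
        class _Const:
            def predict(self, query):
                return np.full(len(query), const)
        return _Const()
    return _FittedKriging(coords, vals, krig, vg, spec.params.get("mean"))


def predict(
    spec: InterpolatorSpec,
    points: SampleTable,
    parameter: str,
    query: np.ndarray,
) -> np.ndarray:
    """Fit ``spec`` and predict at ``query`` coordinates (``(m, 2)`` metres)."""
    fitted = fit_interpolator(spec, points, parameter)
    return np.asarray(fitted.predict(np.atleast_2d(np.asarray(query, float))))


# ---------------------------------------------------------------------------
# LOOCV and model selection


def loocv_rmse(
    spec: InterpolatorSpec, points: SampleTable, parameter: str
) -> CVResult:
    """Leave-one-out cross-validated RMSE of ``spec`` on one parameter.

    Each point is withheld in turn, the interpolator is refitted on the rest
    and the residual is predicted minus measured.  For kriging the variogram
    is fitted once on the full point set and reused across folds (the
    kriging weights are still re-solved per fold).
    """
    vals = points.values(parameter)
    ok = np.isfinite(vals)
    coords, vals = points.coords[ok], vals[ok]
    n = len(vals)
    if n < 3:
        raise InterpolationError(f"LOOCV needs >= 3 points, got {n}")
    fold_spec = spec
    if spec.family == "Kriging" and "variogram" not in spec.params:
        model = spec.variant.split("_")[1]
        vg = fit_variogram(coords, vals, model)
        fold_spec = replace(spec, params={**spec.params, "variogram": vg})
    residuals = np.empty(n)
    from pandas import DataFrame

    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = SampleTable(
            DataFrame({
                "id": np.arange(n - 1),
                "x": coords[keep, 0],
                "y": coords[keep, 1],
                parameter: vals[keep],
            })
        )
        try:
            pred = predict(fold_spec, sub, parameter, coords[i:i + 1])[0]
        except Exception as exc:  # noqa: BLE001 - fold failure is data-driven
            return CVResult(
                spec, float("nan"), n, residuals, valid=False,
                message=f"fold {i} failed: {exc}",
            )
        residuals[i] = pred - vals[i]
    rmse = float(np.sqrt(np.mean(residuals**2)))
    return CVResult(spec, rmse, n, residuals)


def select_best(
    points: SampleTable,
    parameter: str,
    candidates: Sequence[InterpolatorSpec] | None = None,
) -> tuple[InterpolatorSpec, list[CVResult]]:
    """Pick the candidate with minimum LOOCV RMSE (first minimum wins).

    Returns the winner and the full leaderboard of per-candidate results.
    """
    if candidates is None:
        candidates = candidate_specs()
    if not candidates:
        raise ValueError("no candidate interpolators given")
    results = [loocv_rmse(spec, points, parameter) for spec in candidates]
    valid = [r for r in results if r.valid]
    if not valid:
        raise InterpolationError(
            f"all candidates failed LOOCV for {parameter!r}: "
            + "; ".join(r.message for r in results)
        )
    best = min(valid, key=lambda r: r.rmse)  # min() keeps the first minimum
    return best.spec, results


def leaderboard(results_by_parameter: dict[str, Sequence[CVResult]]):
    """RMSE table: one row per interpolator, one column per parameter."""
    import pandas as pd

    cols = {}
    for param, results in results_by_parameter.items():
        cols[param] = {r.spec.label: r.rmse for r in results}
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Rasterisation


def rasterize(
    spec: InterpolatorSpec,
    points: SampleTable,
    parameter: str,
    extent: tuple[float, float, float, float],
    cellsize: float,
    hull_buffer: float | None = None,
    cell_cap: int = 4_000_000,
) -> RasterGrid:
    """Predict on a regular grid of cell centres over ``extent``.

    Cells whose centre falls outside the convex hull of the samples,
    dilated by ``hull_buffer`` metres (default: one mean nearest-neighbour
    distance), are set to no-data.  ``cell_cap`` guards against accidental
    huge rasters.
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin or cellsize <= 0:
        raise ValueError("invalid extent or cellsize")
    n_cols = max(1, int(np.ceil((xmax - xmin) / cellsize)))
    n_rows = max(1, int(np.ceil((ymax - ymin) / cellsize)))
    if n_rows * n_cols > cell_cap:
        raise ValueError(
            f"raster of {n_rows}x{n_cols} cells exceeds the cap of {cell_cap}"
        )
    grid = RasterGrid(xmin, ymin, cellsize, np.zeros((n_rows, n_cols)))
    gx, gy = grid.cell_centers()
    fitted = fit_interpolator(spec, points, parameter)
    preds = fitted.predict(np.column_stack([gx.ravel(), gy.ravel()]))
    values = np.asarray(preds, dtype=float).reshape(n_rows, n_cols)
    if hull_buffer is None:
        hull_buffer = _mean_nn_distance(points.coords)
    hull = shapely.MultiPoint(points.coords).convex_hull.buffer(hull_buffer)
    inside = shapely.contains_xy(hull, gx.ravel(), gy.ravel()).reshape(
        n_rows, n_cols
    )
    values = np.where(inside, values, grid.nodata)
    return grid.with_values(values)
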