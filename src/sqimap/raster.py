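"""Regular raster grids and ESRI ASCII grid I/O.

Values are stored with row 0 as the *northernmost* row, matching the ESRI
ASCII file layout; the origin is the lower-left corner of the grid, cell
size is square and in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid"]

NODATA_DEFAULT = -9999.0


@dataclass(frozen=True)
class RasterGrid:
    """Regular grid of values with origin, cell size and no-data sentinel.

    Parameters
    ----------
    origin_x, origin_y
        Coordinates (m) of the lower-left corner of the grid extent.
    cellsize
        Square cell edge length (m).
    values
        ``(n_rows, n_cols)`` array; row 0 is the northernmost row.
    nodata
        Sentinel for missing cells.
    crs_tag
        Free-text tag describing the planar coordinate system.
    """

    origin_x: float
    origin_y: float
    cellsize: float
    values: np.ndarray
    nodata: float = NODATA_DEFAULT
    crs_tag: str = "local-metres"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"raster values must be 2-D non-empty, got {arr.shape}")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid in metres."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.cellsize * self.n_cols,
            self.origin_y + self.cellsize * self.n_rows,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y coordinates of every cell centre, each ``(n_rows, n_cols)``."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cellsize
        # row 0 is the top (northernmost) row
        y = self.origin_y + (self.n_rows - rows - 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        return replace(self, values=np.asarray(values, dtype=float))

    # -- ESRI ASCII grid ---------------------------------------------------

    def write_ascii(self, path: str | Path) -> Path:
        """Write the grid as an ESRI ASCII grid (plain text)."""
        path = Path(path)
        vals = np.where(self.mask(), self.values, self.nodata)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin_x!r}\n"
            f"yllcorner {self.origin_y!r}\n"
            f"cellsize {self.cellsize!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")
        return path


def read_ascii_grid(path: str | Path, crs_tag: str = "local-metres") -> RasterGrid:
    """Read an ESRI ASCII grid written by :meth:`RasterGrid.write_ascii`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            header[key.strip().lower()] = float(val)
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"grid body shape {values.shape} does not match header "
            f"({n_rows}, {n_cols})"
        )
    return RasterGrid(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cellsize=header["cellsize"],
        values=values,
        nodata=header.get("nodata_value", NODATA_DEFAULT),
        crs_tag=crs_tag,
    )
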