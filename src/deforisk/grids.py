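"""Raster grid conventions and plain-text/TIFF raster I/O.

Every raster in this package is a row-major :class:`numpy.ndarray` tied to a
:class:`GridSpec` describing a square-cell, equal-area grid.  Cell ``(i, j)``
has its center at ``origin + ((j + 0.5) * cell_size, (i + 0.5) * cell_size)``;
polygons are rasterized by a center-in-polygon test (boundary inclusive).

Rasters are persisted either as ESRI ASCII grids (``.asc``, plain text) or as
single-band TIFF (``.tif``/``.tiff``); the ASCII form is the default because
it survives text-only archiving.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GridSpec",
    "rasterize_geometry",
    "read_raster",
    "write_raster",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an equal-area raster grid with square cells.

    Parameters
    ----------
    n_rows, n_cols:
        Grid shape; both must be at least 1.
    cell_size:
        Edge length of a square cell in metres.  Cell area is exactly
        ``cell_size ** 2``.
    origin:
        ``(x, y)`` of the grid corner adjacent to cell ``(0, 0)``, in metres.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size * self.cell_size

    @property
    def cell_area_km2(self) -> float:
        return self.cell_area_m2 / 1e6

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` center-coordinate arrays of shape ``shape``."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def extent(self) -> Tuple[float, float, float, float]:
        """``(xmin, ymin, xmax, ymax)`` of the grid footprint in metres."""
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.n_cols * self.cell_size,
            y0 + self.n_rows * self.cell_size,
        )

    def validate_raster(self, raster: np.ndarray, name: str = "raster") -> None:
        if raster.shape != self.shape:
            raise ValueError(
                f"{name} shape {raster.shape} does not match grid {self.shape}"
            )


def rasterize_geometry(geometry: BaseGeometry, grid: GridSpec) -> np.ndarray:
    """Rasterize a polygonal geometry with a center-in-polygon test.

    A cell is set when its center lies inside or on the boundary of the
    geometry.  Returns a boolean array of shape ``grid.shape``.
    """
    if geometry.is_empty:
        return np.zeros(grid.shape, dtype=bool)
    x, y = grid.cell_centers()
    mask = shapely.intersects_xy(geometry, x.ravel(), y.ravel())
    return mask.reshape(grid.shape)


# ---------------------------------------------------------------------------
# Raster file I/O
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_raster(path: str | Path, raster: np.ndarray, grid: GridSpec) -> Path:
    """Write ``raster`` to ``path`` (format chosen by extension).

    ``.asc`` → ESRI ASCII grid (text); ``.tif``/``.tiff`` → single-band TIFF
    via tifffile.  Boolean rasters are stored as 0/1.
    """
    path = Path(path)
    grid.validate_raster(raster)
    data = raster.astype(np.float64) if raster.dtype == bool else raster
    if path.suffix == ".asc":
        x0, y0 = grid.origin
        header = (
            f"ncols {grid.n_cols}\n"
            f"nrows {grid.n_rows}\n"
            f"xllcorner {x0}\n"
            f"yllcorner {y0}\n"
            f"cellsize {grid.cell_size}\n"
            f"NODATA_value {_NODATA}\n"
        )
        body = np.where(np.isfinite(data), data, _NODATA)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.8g")
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(
            path,
            np.asarray(data, dtype=np.float32),
            metadata={
                "cell_size": grid.cell_size,
                "origin_x": grid.origin[0],
                "origin_y": grid.origin[1],
            },
        )
    else:
        raise ValueError(f"unsupported raster extension: {path.suffix}")
    return path


def read_raster(path: str | Path) -> Tuple[np.ndarray, GridSpec]:
    """Read a raster written by :func:`write_raster`; returns ``(array, grid)``."""
    path = Path(path)
    if path.suffix == ".asc":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                header[key.lower()] = float(value)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        data[data == header.get("nodata_value", _NODATA)] = np.nan
        grid = GridSpec(
            n_rows=int(header["nrows"]),
            n_cols=int(header["ncols"]),
            cell_size=header["cellsize"],
            origin=(header["xllcorner"], header["yllcorner"]),
        )
        grid.validate_raster(data)
        return data, grid
    if path.suffix in (".tif", ".tiff"):
        import json

        import tifffile

        with tifffile.TiffFile(path) as tif:
            data = tif.asarray().astype(np.float64)
            desc = tif.pages[0].tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        grid = GridSpec(
            n_rows=data.shape[0],
            n_cols=data.shape[1],
            cell_size=float(meta.get("cell_size", 1.0)),
            origin=(float(meta.get("origin_x", 0.0)), float(meta.get("origin_y", 0.0))),
        )
        return data, grid
    raise ValueError(f"unsupported raster extension: {path.suffix}")
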