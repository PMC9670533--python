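"""Planar raster grids and posterior sample stacks.

Everything in this package works in projected planar coordinates measured in
kilometres.  A :class:`RasterGrid` is a regular square-celled grid anchored at
a lower-left corner; values are stored row-major with row 0 at the *top* of
the map (the usual raster convention), and ``NaN`` marks nodata.

Rasters are read and written as ESRI ASCII grids (``.asc``), a plain-text
interchange format understood by GDAL and QGIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator
import warnings

import numpy as np

__all__ = ["RasterGrid", "PosteriorSampleStack"]


@dataclass
class RasterGrid:
    """A regular georeferenced grid of values.

    Parameters
    ----------
    values : ndarray of shape (ny, nx)
        Cell values; ``NaN`` is nodata.  Row 0 is the northernmost row.
    x0, y0 : float
        Coordinates (km) of the lower-left corner of the grid.
    cell_km : float
        Side length of a (square) cell in km.
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_km: float = 5.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def n_cells(self) -> int:
        return self.values.size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell_km,
            self.y0 + self.ny * self.cell_km,
        )

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.cell_km - other.cell_km) <= tol
        )

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates, row-major order."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_km
        ys_top_down = self.y0 + (self.ny - np.arange(self.ny) - 0.5) * self.cell_km
        xx, yy = np.meshgrid(xs, ys_top_down)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing the given points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.extent
        if np.any((x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)):
            raise ValueError("point outside raster extent")
        col = np.clip(((x - self.x0) / self.cell_km).astype(int), 0, self.nx - 1)
        row_from_bottom = np.clip(((y - self.y0) / self.cell_km).astype(int), 0, self.ny - 1)
        row = self.ny - 1 - row_from_bottom
        return row, col

    def value_at(self, x, y) -> np.ndarray:
        """Value of the containing cell (nearest-cell lookup)."""
        row, col = self.index_of(x, y)
        return self.values[row, col]

    def like(self, values: np.ndarray | None = None) -> "RasterGrid":
        """A new grid sharing this grid's geometry."""
        if values is None:
            values = np.full_like(self.values, np.nan)
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            values = values.reshape(self.values.shape)
        return RasterGrid(values.copy(), self.x0, self.y0, self.cell_km)

    # -- I/O --------------------------------------------------------------
    NODATA = -9999.0

    def write_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (text)."""
        path = Path(path)
        vals = np.where(np.isnan(self.values), self.NODATA, self.values)
        header = (
            f"ncols {self.nx}\n"
            f"nrows {self.ny}\n"
            f"xllcorner {self.x0}\n"
            f"yllcorner {self.y0}\n"
            f"cellsize {self.cell_km}\n"
            f"NODATA_value {self.NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        vals = np.loadtxt(lines[i:])
        vals = np.atleast_2d(vals)
        nodata = header.get("nodata_value", cls.NODATA)
        vals = np.where(vals == nodata, np.nan, vals)
        return cls(
            vals,
            x0=header.get("xllcorner", 0.0),
            y0=header.get("yllcorner", 0.0),
            cell_km=header.get("cellsize", 1.0),
        )


@dataclass
class PosteriorSampleStack:
    """S posterior draws of a probability surface on a common grid.

    ``samples`` has shape (S, n_cells) in the row-major cell order of
    ``template``; masked (nodata) cells are NaN in every sample.  This is the
    object passed between model prediction, CCI combination and admin-level
    aggregation.
    """

    samples: np.ndarray
    template: RasterGrid
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (S, n_cells)")
        if self.samples.shape[1] != self.template.n_cells:
            raise ValueError("sample width does not match grid cell count")
        if self.n_samples < 2:
            raise ValueError("a posterior stack needs at least 2 samples")
        finite = self.samples[np.isfinite(self.samples)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("probability samples must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Boolean (n_cells,) — True where the cell carries data."""
        return np.isfinite(self.samples).all(axis=0)

    def summarize(self) -> dict[str, RasterGrid]:
        """Cellwise mean, median, 2.5/97.5 percentiles and 95% CrI width.

        Percentiles use linear interpolation between order statistics.
        """
        if self.n_samples < 40:
            warnings.warn(
                f"only {self.n_samples} posterior samples: 2.5/97.5 percentiles "
                "will be unstable",
                stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.mean(self.samples, axis=0)
            med = np.median(self.samples, axis=0)
            q025 = np.percentile(self.samples, 2.5, axis=0)
            q975 = np.percentile(self.samples, 97.5, axis=0)
        out = {
            "mean": mean,
            "median": med,
            "q025": q025,
            "q975": q975,
            "width": q975 - q025,
        }
        return {k: self.template.like(v) for k, v in out.items()}

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.samples)
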