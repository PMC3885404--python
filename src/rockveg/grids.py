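"""Planar processing grids and height rasters.

All gridded products in the pipeline (DEM, canopy-height model, per-cell
profile features, class maps) live on axis-aligned square grids.  A cell
``(i, j)`` covers the half-open square
``[x0 + i*s, x0 + (i+1)*s) x [y0 + j*s, y0 + (j+1)*s)`` with ``s`` the cell
size; indices are 0-based, ``i`` along x (columns), ``j`` along y (rows).
Rasters are stored as ``values[j, i]`` (row-major, row 0 = southernmost).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular square grid.

    Parameters
    ----------
    x0, y0 : float
        Planar coordinates of the grid origin (south-west corner), metres.
    cell_size : float
        Side length of a cell in metres (> 0).
    ncols, nrows : int
        Number of cells along x and y.
    """

    x0: float
    y0: float
    cell_size: float
    ncols: int
    nrows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one cell")

    @classmethod
    def from_bounds(
        cls, xmin: float, ymin: float, xmax: float, ymax: float, cell_size: float
    ) -> "GridSpec":
        """Grid covering a bounding box, origin snapped to floor multiples
        of ``cell_size``."""
        x0 = np.floor(xmin / cell_size) * cell_size
        y0 = np.floor(ymin / cell_size) * cell_size
        ncols = max(1, int(np.ceil((xmax - x0) / cell_size)))
        nrows = max(1, int(np.ceil((ymax - y0) / cell_size)))
        # points exactly on the upper edge fall in an extra cell
        if x0 + ncols * cell_size <= xmax:
            ncols += 1
        if y0 + nrows * cell_size <= ymax:
            nrows += 1
        return cls(float(x0), float(y0), float(cell_size), ncols, nrows)

    def cell_index(self, x, y):
        """Column/row indices of the cells containing planar points.

        Returns ``(i, j)`` integer arrays; points outside the grid get
        indices outside ``[0, ncols)`` / ``[0, nrows)``.
        """
        i = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(np.int64)
        j = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(np.int64)
        return i, j

    def cell_center(self, i, j):
        x = self.x0 + (np.asarray(i) + 0.5) * self.cell_size
        y = self.y0 + (np.asarray(j) + 0.5) * self.cell_size
        return x, y

    def centers(self):
        """Meshgrid of all cell-center coordinates, shaped (nrows, ncols)."""
        i = np.arange(self.ncols)
        j = np.arange(self.nrows)
        ii, jj = np.meshgrid(i, j)
        return self.cell_center(ii, jj)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2


@dataclass
class HeightRaster:
    """A single-band elevation or height-above-ground raster.

    ``values`` is shaped ``(nrows, ncols)``; ``NODATA`` marks empty cells.
    ``extrapolated`` optionally flags cells filled outside the data's
    convex hull.
    """

    grid: GridSpec
    values: np.ndarray
    nodata: float = NODATA
    extrapolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.nrows}, {self.grid.ncols})"
            )

    def sample(self, x, y):
        """Raster value at the cell containing each (x, y); NaN outside."""
        i, j = self.grid.cell_index(x, y)
        i = np.atleast_1d(i)
        j = np.atleast_1d(j)
        out = np.full(i.shape, np.nan)
        ok = (i >= 0) & (i < self.grid.ncols) & (j >= 0) & (j < self.grid.nrows)
        out[ok] = self.values[j[ok], i[ok]]
        out[out == self.nodata] = np.nan
        return out


def write_ascii_grid(raster: HeightRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc) — plain-text raster interchange."""
    g = raster.grid
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.x0}\n"
        f"yllcorner {g.y0}\n"
        f"cellsize {g.cell_size}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    # ASCII grids store the northernmost row first
    body = np.flipud(raster.values)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.4f")


def read_ascii_grid(path: str | Path) -> HeightRaster:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    grid = GridSpec(
        hdr["xllcorner"],
        hdr["yllcorner"],
        hdr["cellsize"],
        int(hdr["ncols"]),
        int(hdr["nrows"]),
    )
    values = np.flipud(np.atleast_2d(values))
    return HeightRaster(grid, values, nodata=hdr["nodata_value"])
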