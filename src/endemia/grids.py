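"""Grid geometry and plain-text raster I/O.

A :class:`GridSpec` describes a regular lon/lat grid the way a raster header
does: rows run north-to-south from the outer corner of cell (0, 0). Rasters
are written as ESRI ASCII grids (``.asc``), a plain-text format readable by
standard GIS tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; at least 8 each.
    cell_size
        Cell edge length in degrees.
    origin
        (lon, lat) of the outer (north-west) corner of cell (0, 0).
        Row index increases southwards, column index eastwards.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Lon/lat of the center of cell (row, col)."""
        lon0, lat0 = self.origin
        return (
            lon0 + (col + 0.5) * self.cell_size,
            lat0 - (row + 0.5) * self.cell_size,
        )

    def lonlat_to_cell(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell index containing (lon, lat); raises if outside the grid."""
        lon0, lat0 = self.origin
        col = math.floor((lon - lon0) / self.cell_size)
        row = math.floor((lat0 - lat) / self.cell_size)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) falls outside the grid")
        return (row, col)

    def contains(self, lon: float, lat: float) -> bool:
        lon0, lat0 = self.origin
        return (
            lon0 <= lon < lon0 + self.n_cols * self.cell_size
            and lat0 - self.n_rows * self.cell_size < lat <= lat0
        )

    def degrees_to_cells(self, degrees: float) -> int:
        """Convert a buffer distance in degrees to whole cells, rounding up."""
        return int(math.ceil(degrees / self.cell_size - 1e-12))

    def ravel(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.asarray(rows) * self.n_cols + np.asarray(cols)

    def unravel(self, flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        flat = np.asarray(flat)
        return flat // self.n_cols, flat % self.n_cols


def write_ascii_grid(path, grid: GridSpec, values: np.ndarray, nodata: float = NODATA) -> None:
    """Write a 2-D array as an ESRI ASCII grid."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"array shape {values.shape} != grid shape {grid.shape}")
    lon0, lat0 = grid.origin
    yll = lat0 - grid.n_rows * grid.cell_size
    out = np.where(np.isnan(values), nodata, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(lon0)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid back into (GridSpec, array); nodata -> NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    lat0 = header["yllcorner"] + n_rows * cell
    grid = GridSpec(n_rows, n_cols, cell, (header["xllcorner"], lat0))
    values = np.array(rows, dtype=float)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    return grid, values
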