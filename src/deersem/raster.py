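"""Minimal planar raster container with ESRI ASCII grid I/O.

Conventions used throughout the package: coordinates are planar metres, the
origin is the raster's lower-left corner, and the centre of cell (row i from
the bottom, column j) sits at ((j + 0.5) * cellsize, (i + 0.5) * cellsize).
Arrays are stored bottom-up (row 0 = southernmost row); ESRI ASCII files are
written top-down as the format requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid", "disc_cell_indices"]


@dataclass
class Raster:
    """A single-band raster on a regular square grid.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values, row 0 at the bottom (south).
    cellsize : float
        Cell edge length in metres.
    xllcorner, yllcorner : float
        Coordinates of the lower-left corner of the grid, metres.
    nodata : float
        Sentinel written to file for NaN cells.
    """

    values: np.ndarray
    cellsize: float = 100.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in metres."""
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + self.ncols * self.cellsize,
            self.yllcorner + self.nrows * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-centre coordinates, same shape as values."""
        xs = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yllcorner + (np.arange(self.nrows) + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cellsize, other.cellsize)
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
        )

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y)."""
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside raster extent {self.extent}")
        col = min(int((x - self.xllcorner) / self.cellsize), self.ncols - 1)
        row = min(int((y - self.yllcorner) / self.cellsize), self.nrows - 1)
        return row, col

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(
            values=np.asarray(values, dtype=float),
            cellsize=self.cellsize,
            xllcorner=self.xllcorner,
            yllcorner=self.yllcorner,
            nodata=self.nodata,
        )


def disc_cell_indices(raster: Raster, x: float, y: float, radius_m: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices (rows, cols) of cells whose centres lie within the closed disc
    of ``radius_m`` around (x, y).

    The inclusion rule is centre-in-disc: a cell belongs to the averaging set
    iff the distance from its centre to the point is <= radius. Raises if no
    cell centre qualifies (radius too small for the grid).
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    if not raster.contains(x, y):
        raise ValueError(f"point ({x}, {y}) outside raster extent")
    cs = raster.cellsize
    # bounding box of candidate rows/cols
    col_lo = max(int(np.floor((x - radius_m - raster.xllcorner) / cs)), 0)
    col_hi = min(int(np.ceil((x + radius_m - raster.xllcorner) / cs)), raster.ncols - 1)
    row_lo = max(int(np.floor((y - radius_m - raster.yllcorner) / cs)), 0)
    row_hi = min(int(np.ceil((y + radius_m - raster.yllcorner) / cs)), raster.nrows - 1)
    cols = np.arange(col_lo, col_hi + 1)
    rows = np.arange(row_lo, row_hi + 1)
    cx = raster.xllcorner + (cols + 0.5) * cs
    cy = raster.yllcorner + (rows + 0.5) * cs
    dx2 = (cx - x) ** 2
    dy2 = (cy - y) ** 2
    mask = dy2[:, None] + dx2[None, :] <= radius_m**2
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError(
            f"disc of radius {radius_m} m around ({x}, {y}) contains no cell centres "
            f"(cellsize {cs} m): radius too small for the grid"
        )
    return rows[rr], cols[cc]


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (.asc), top row first."""
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.xllcorner}\n"
        f"yllcorner {raster.yllcorner}\n"
        f"cellsize {raster.cellsize}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.6g")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any
    conforming file)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1].copy()
    nodata = header.get("nodata_value", -9999.0)
    vals[vals == nodata] = np.nan
    return Raster(
        values=vals,
        cellsize=header.get("cellsize", 100.0),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        nodata=nodata,
    )
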