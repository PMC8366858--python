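"""Regular-grid rasters (bathymetry and derived sea-floor slope).

The container is deliberately minimal: a row-major value array with a
lower-left origin and square cells, matching the ESRI ASCII grid layout in
which bathymetry is exchanged. Row 0 of ``values`` is the NORTHERNMOST row,
as in the file format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA_DEFAULT = -9999.0


@dataclass
class RasterGrid:
    """A regular raster: ``values[0, 0]`` is the north-west corner cell.

    Parameters
    ----------
    xll, yll:
        Coordinates of the lower-left corner of the lower-left cell.
    cellsize:
        Cell edge length, same units as ``xll``/``yll`` (meters here).
    values:
        2-D float array (n_rows, n_cols); NaN marks missing cells.
    """

    xll: float
    yll: float
    cellsize: float
    values: np.ndarray
    nodata: float = field(default=NODATA_DEFAULT)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self):
        """(x, y) meshgrids of cell-center coordinates, shape (n_rows, n_cols)."""
        xs = self.xll + (np.arange(self.n_cols) + 0.5) * self.cellsize
        ys_bottom_up = self.yll + (np.arange(self.n_rows) + 0.5) * self.cellsize
        ys = ys_bottom_up[::-1]  # row 0 is the top
        return np.meshgrid(xs, ys)

    def sample(self, x, y):
        """Nearest-cell lookup at planar coordinates (vectorized)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.clip(((x - self.xll) / self.cellsize).astype(int), 0, self.n_cols - 1)
        row_from_bottom = np.clip(
            ((y - self.yll) / self.cellsize).astype(int), 0, self.n_rows - 1
        )
        row = self.n_rows - 1 - row_from_bottom
        return self.values[row, col]


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc). Accepts xllcorner or xllcenter headers."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cellsize = header["cellsize"]
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # cell-center registration
        xll = header["xllcenter"] - cellsize / 2
        yll = header["yllcenter"] - cellsize / 2
    values = np.loadtxt(lines[n_header:]).reshape(nrows, ncols)
    values = np.where(values == nodata, np.nan, values)
    return RasterGrid(xll=xll, yll=yll, cellsize=cellsize, values=values, nodata=nodata)


def write_ascii_grid(path, raster: RasterGrid):
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {raster.n_cols}\nnrows {raster.n_rows}\n"
            f"xllcorner {raster.xll}\nyllcorner {raster.yll}\n"
            f"cellsize {raster.cellsize}\nNODATA_value {raster.nodata}\n"
        )
        np.savetxt(fh, vals, fmt="%.6g")


def compute_slope(bathymetry: RasterGrid) -> RasterGrid:
    """Sea-floor slope (degrees) from a bathymetry raster.

    Gradient by central differences over the 4 rook neighbours (one-sided at
    edges), magnitude g = sqrt(gx^2 + gy^2), slope = atan(g) in degrees —
    always in [0, 90). Bathymetry must be in meters with a metric cellsize so
    the rise/run ratio is dimensionless.
    """
    if bathymetry.n_rows < 2 or bathymetry.n_cols < 2:
        raise ValueError("slope needs a raster with at least 2 rows and 2 columns")
    # np.gradient: central differences interior, one-sided at the boundary.
    gy, gx = np.gradient(bathymetry.values, bathymetry.cellsize)
    g = np.sqrt(gx**2 + gy**2)
    slope_deg = np.degrees(np.arctan(g))
    return RasterGrid(
        xll=bathymetry.xll,
        yll=bathymetry.yll,
        cellsize=bathymetry.cellsize,
        values=slope_deg,
        nodata=bathymetry.nodata,
    )
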