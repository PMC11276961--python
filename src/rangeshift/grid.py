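"""Lon/lat raster grids: the universal spatial currency of the pipeline.

A :class:`RasterGrid` is a 2-D value array on a regular WGS84 lon/lat grid
with a north-up geotransform and a boolean validity mask.  Row 0 is the
northernmost row; column 0 the westernmost column.  Grids are written and
read as plain-text ESRI ASCII grids (.asc) so every artifact stays
human-readable and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

EARTH_RADIUS_KM = 6371.0
NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single gridded layer.

    Parameters
    ----------
    values : 2-D float array, row 0 = north.
    west, north : lon/lat of the outer (west/north) edge of the grid, degrees.
    cellsize : cell size in degrees (square cells).
    mask : boolean array, True where the cell holds valid data.
    """

    values: np.ndarray
    west: float
    north: float
    cellsize: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must equal value shape")

    # -- geometry -----------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.cellsize

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cellsize

    def lons(self) -> np.ndarray:
        """Cell-centre longitudes, west to east."""
        return self.west + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lats(self) -> np.ndarray:
        """Cell-centre latitudes, north to south (row order)."""
        return self.north - (np.arange(self.nrows) + 0.5) * self.cellsize

    def lat_grid(self) -> np.ndarray:
        return np.broadcast_to(self.lats()[:, None], self.values.shape)

    def lon_grid(self) -> np.ndarray:
        return np.broadcast_to(self.lons()[None, :], self.values.shape)

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.west, other.west)
            and np.isclose(self.north, other.north)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def require_aligned(self, other: "RasterGrid") -> None:
        if not self.same_geometry(other):
            raise ValueError("grids are not aligned (shape or geotransform differ)")

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given points."""
        col = np.floor((np.asarray(lon) - self.west) / self.cellsize).astype(int)
        row = np.floor((self.north - np.asarray(lat)) / self.cellsize).astype(int)
        return row, col

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        return RasterGrid(
            np.asarray(values, dtype=float),
            self.west,
            self.north,
            self.cellsize,
            self.mask.copy() if mask is None else mask,
        )

    def blank_like(self) -> "RasterGrid":
        return self.copy_with(np.zeros_like(self.values))

    # -- I/O ----------------------------------------------------------------
    def write_ascii(self, path: str | Path) -> None:
        out = np.where(self.mask, self.values, NODATA)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.west:.10g}\n"
            f"yllcorner {self.south:.10g}\n"
            f"cellsize {self.cellsize:.10g}\n"
            f"NODATA_value {NODATA:g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        nodata = header.get("nodata_value", NODATA)
        mask = values != nodata
        vals = np.where(mask, values, np.nan)
        north = header["yllcorner"] + header["nrows"] * header["cellsize"]
        return cls(vals, header["xllcorner"], north, header["cellsize"], mask)


def cell_area_grid(grid: RasterGrid) -> RasterGrid:
    """Per-cell surface area in km² on the authalic sphere (R = 6371 km).

    A = R² · Δλ · (sin φ_top − sin φ_bottom); constant along rows, shrinking
    poleward, so area-weighted sums are latitude-correct.
    """
    dlam = np.deg2rad(grid.cellsize)
    lat_top = np.deg2rad(grid.north - np.arange(grid.nrows) * grid.cellsize)
    lat_bot = lat_top - np.deg2rad(grid.cellsize)
    row_area = EARTH_RADIUS_KM**2 * dlam * (np.sin(lat_top) - np.sin(lat_bot))
    values = np.repeat(row_area[:, None], grid.ncols, axis=1)
    return RasterGrid(values, grid.west, grid.north, grid.cellsize,
                      np.ones_like(values, dtype=bool))


def resample_to(layer: RasterGrid, target: RasterGrid, method: str = "bilinear") -> RasterGrid:
    """Resample a layer onto the target's grid.

    Methods: ``bilinear`` and ``nearest`` interpolate at target cell centres;
    ``mean`` averages the source cells whose centres fall inside each target
    cell (block aggregation for coarsening).  Nodata propagates.
    """
    if (layer.east <= target.west or target.east <= layer.west
            or layer.north <= target.south or target.north <= layer.south):
        raise ValueError("source and target extents are disjoint")
    src = np.where(layer.mask, layer.values, np.nan)
    if method == "mean":
        rows, cols = layer.cell_index(layer.lon_grid().ravel(), layer.lat_grid().ravel())
        trow, tcol = target.cell_index(layer.lon_grid().ravel(), layer.lat_grid().ravel())
        ok = (
            (trow >= 0) & (trow < target.nrows) & (tcol >= 0) & (tcol < target.ncols)
            & np.isfinite(src.ravel())
        )
        acc = np.zeros(target.values.shape)
        cnt = np.zeros(target.values.shape)
        np.add.at(acc, (trow[ok], tcol[ok]), src.ravel()[ok])
        np.add.at(cnt, (trow[ok], tcol[ok]), 1.0)
        with np.errstate(invalid="ignore"):
            out = acc / cnt
        mask = cnt > 0
        out[~mask] = np.nan
        return RasterGrid(out, target.west, target.north, target.cellsize, mask)

    # fractional source indices of target cell centres
    col = (target.lon_grid() - layer.west) / layer.cellsize - 0.5
    row = (layer.north - target.lat_grid()) / layer.cellsize - 0.5
    order = {"bilinear": 1, "nearest": 0}.get(method)
    if order is None:
        raise ValueError(f"unknown resampling method: {method!r}")
    out = ndimage.map_coordinates(src, [row, col], order=order, mode="nearest")
    inside = (col >= -0.5) & (col <= layer.ncols - 0.5) & (row >= -0.5) & (row <= layer.nrows - 0.5)
    out[~inside] = np.nan
    mask = np.isfinite(out)
    return RasterGrid(out, target.west, target.north, target.cellsize, mask)
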