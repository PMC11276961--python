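"""Slope and aspect from a DEM on a lon/lat grid (Horn's method).

Slope is in degrees; aspect is the compass direction the surface faces
(downslope), clockwise from north in [0, 360). Flat cells receive the
sentinel aspect −1. Degree spacing is converted to metres with R = 6371 km
and a cos(latitude) factor for the east–west direction.
"""

from __future__ import annotations

import numpy as np

from .grid import EARTH_RADIUS_KM, RasterGrid

FLAT_ASPECT = -1.0
_M_PER_DEG = EARTH_RADIUS_KM * 1000.0 * np.pi / 180.0


def compute_terrain(dem: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Return (slope°, aspect°) grids for a DEM in metres."""
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("DEM must be at least 3x3 cells")
    z = np.where(dem.mask, dem.values, np.nan)
    zp = np.pad(z, 1, mode="edge")

    # Horn's 8-neighbour weighted differences. Row 0 is north, so the
    # northward derivative takes rows i-1 minus i+1.
    nw, n_, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s_, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]

    dx_m = _M_PER_DEG * dem.cellsize * np.cos(np.deg2rad(dem.lat_grid()))
    dy_m = _M_PER_DEG * dem.cellsize
    dz_dx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * dx_m)
    dz_dy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * dy_m)

    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))

    # aspect = compass bearing of the downslope vector (-∇z)
    aspect = np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0
    flat = np.hypot(dz_dx, dz_dy) == 0
    aspect = np.where(flat, FLAT_ASPECT, aspect)

    mask = dem.mask & np.isfinite(slope)
    slope = np.where(mask, slope, np.nan)
    aspect = np.where(mask, aspect, np.nan)
    return dem.copy_with(slope, mask), dem.copy_with(aspect, mask.copy())
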