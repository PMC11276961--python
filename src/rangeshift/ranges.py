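"""Potential ranges and per-species range-shift indices.

Suitability is binarized at the maximum sensitivity–specificity sum (MSS)
threshold into a potential range PR.  For a current/future range pair with
areas RC and RF and shared area RS, the pipeline reports:

* range expansion ratio  RER = RF / RC,
* range similarity index RSI = 2·RS / (RC + RF)  (Sørensen overlap: 1 means
  identical ranges, 0 disjoint),
* expanding range        = future ∖ current  (potential newly invaded area),
* centroid shift         = great-circle distance and initial bearing between
  area-weighted range centroids.

All areas are spherical km² so poleward cells count correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import EARTH_RADIUS_KM, RasterGrid
from .maps import RangeMap, SuitabilityMap
from .metrics import mss_threshold  # re-exported: MSS is the binarization rule
from .occurrences import great_circle_km

__all__ = [
    "RangeDynamics", "mss_threshold", "binarize", "range_area", "compute_rer",
    "compute_rsi", "expanding_range", "centroid_shift", "range_dynamics",
    "paired_t_test",
]


@dataclass(frozen=True)
class RangeDynamics:
    """Range-shift summary for one species × (current → future) pair."""

    species: str
    scenario: str
    rc_area_km2: float
    rf_area_km2: float
    rs_area_km2: float
    rer: float
    rsi: float
    expanding_area_km2: float
    centroid_shift_km: float
    centroid_bearing_deg: float


def binarize(suitability: SuitabilityMap, threshold: float) -> RangeMap:
    """Potential range: cell = 1 iff suitability ≥ threshold; nodata kept."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0,1]")
    g = suitability.grid
    values = np.where(g.mask, (g.values >= threshold).astype(float), np.nan)
    return RangeMap(grid=g.copy_with(values), species=suitability.species,
                    scenario=suitability.scenario, threshold=float(threshold))


def range_area(rmap: RangeMap, areas: RasterGrid) -> float:
    """Total km² of the cells inside the range."""
    rmap.grid.require_aligned(areas)
    return float(areas.values[rmap.inside()].sum())


def compute_rer(rc_area: float, rf_area: float) -> float:
    """Range expansion ratio RF/RC (>1 = net expansion)."""
    if rc_area <= 0:
        raise ValueError("undefined RER: current range area is zero")
    return rf_area / rc_area


def compute_rsi(current: RangeMap, future: RangeMap, areas: RasterGrid) -> float:
    """Sørensen range similarity 2·RS/(RC+RF) in [0,1]."""
    current.grid.require_aligned(future.grid)
    rc = range_area(current, areas)
    rf = range_area(future, areas)
    if rc + rf == 0:
        raise ValueError("both ranges empty: RSI undefined")
    shared = float(areas.values[current.inside() & future.inside()].sum())
    return 2.0 * shared / (rc + rf)


def expanding_range(current: RangeMap, future: RangeMap) -> RangeMap:
    """Cells newly occupied in the future: future = 1 AND current = 0."""
    current.grid.require_aligned(future.grid)
    mask = current.grid.mask & future.grid.mask
    values = np.where(mask, (future.inside() & ~current.inside()).astype(float),
                      np.nan)
    return RangeMap(grid=current.grid.copy_with(values, mask),
                    species=future.species, scenario=future.scenario,
                    threshold=future.threshold)


def _centroid(rmap: RangeMap, areas: RasterGrid) -> tuple[float, float]:
    """Area-weighted range centroid: mean of unit vectors on the sphere."""
    inside = rmap.inside()
    if not inside.any():
        raise ValueError("empty range has no centroid")
    w = areas.values[inside]
    lat = np.deg2rad(rmap.grid.lat_grid()[inside])
    lon = np.deg2rad(rmap.grid.lon_grid()[inside])
    x = np.sum(w * np.cos(lat) * np.cos(lon))
    y = np.sum(w * np.cos(lat) * np.sin(lon))
    z = np.sum(w * np.sin(lat))
    return float(np.degrees(np.arctan2(y, x))), \
        float(np.degrees(np.arctan2(z, np.hypot(x, y))))


def _initial_bearing(lon1, lat1, lon2, lat2) -> float:
    """Initial great-circle bearing, degrees clockwise from north."""
    phi1, phi2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dlam = np.deg2rad(lon2 - lon1)
    x = np.sin(dlam) * np.cos(phi2)
    y = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return float(np.degrees(np.arctan2(x, y)) % 360.0)


def centroid_shift(current: RangeMap, future: RangeMap,
                   areas: RasterGrid) -> tuple[float, float]:
    """(distance km, initial bearing °) between the two range centroids."""
    current.grid.require_aligned(future.grid)
    lon1, lat1 = _centroid(current, areas)
    lon2, lat2 = _centroid(future, areas)
    dist = float(great_circle_km(lon1, lat1, lon2, lat2))
    return dist, _initial_bearing(lon1, lat1, lon2, lat2)


def range_dynamics(current: RangeMap, future: RangeMap,
                   areas: RasterGrid) -> RangeDynamics:
    """All range-shift quantities for one species × future scenario."""
    rc = range_area(current, areas)
    rf = range_area(future, areas)
    shared = float(areas.values[current.inside() & future.inside()].sum())
    expanding = expanding_range(current, future)
    dist, bearing = centroid_shift(current, future, areas)
    return RangeDynamics(
        species=future.species, scenario=future.scenario,
        rc_area_km2=rc, rf_area_km2=rf, rs_area_km2=shared,
        rer=compute_rer(rc, rf), rsi=compute_rsi(current, future, areas),
        expanding_area_km2=range_area(expanding, areas),
        centroid_shift_km=dist, centroid_bearing_deg=bearing,
    )


def paired_t_test(current_areas, future_areas) -> tuple[float, float]:
    """Two-sided paired-samples t-test of current vs future range sizes."""
    x = np.asarray(current_areas, dtype=float)
    y = np.asarray(future_areas, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors with n ≥ 2")
    if np.var(x - y) == 0:
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
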