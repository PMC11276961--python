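"""Multi-species overlap indices, change maps and invasion hotspots.

OIHS (overlap index of habitat suitability) is the cell-wise sum of the
species' continuous suitabilities; OIPR (overlap index of potential range)
counts how many species' binary ranges cover a cell; the same count over
expanding ranges localises jointly invadable territory.  Change maps are
future − current, so positive values mean an increase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid
from .maps import RangeMap, SuitabilityMap


@dataclass
class OverlapMap:
    """Cell-wise aggregate over species; kind ∈ {oihs, oipr, expanding}."""

    grid: RasterGrid
    kind: str
    scenario: str
    n_species: int


@dataclass
class ChangeMap:
    """Future − current difference of two same-kind maps."""

    grid: RasterGrid
    kind: str
    scenario_pair: tuple[str, str]


def _sum_layers(grids: list[RasterGrid]) -> RasterGrid:
    if not grids:
        raise ValueError("need at least one map")
    for g in grids[1:]:
        grids[0].require_aligned(g)
    mask = np.ones(grids[0].values.shape, dtype=bool)
    for g in grids:
        mask &= g.mask
    total = np.zeros(grids[0].values.shape)
    for g in grids:
        total += np.where(g.mask, g.values, 0.0)
    total = np.where(mask, total, np.nan)
    return grids[0].copy_with(total, mask)


def overlap_suitability(maps: list[SuitabilityMap]) -> OverlapMap:
    """OIHS = Σᵢ HSᵢ over species, in [0, N]."""
    scenario = maps[0].scenario if maps else ""
    return OverlapMap(_sum_layers([m.grid for m in maps]), "oihs",
                      scenario, len(maps))


def overlap_ranges(maps: list[RangeMap]) -> OverlapMap:
    """OIPR = Σᵢ PRᵢ: per-cell count of species whose range covers the cell."""
    scenario = maps[0].scenario if maps else ""
    return OverlapMap(_sum_layers([m.grid for m in maps]), "oipr",
                      scenario, len(maps))


def overlap_expanding(maps: list[RangeMap]) -> OverlapMap:
    """Overlap count of expanding ranges (same operator as OIPR)."""
    out = overlap_ranges(maps)
    return OverlapMap(out.grid, "expanding", out.scenario, out.n_species)


def suitability_change(current: OverlapMap | SuitabilityMap,
                       future: OverlapMap | SuitabilityMap) -> ChangeMap:
    """future − current on aligned same-kind maps; positive = increase."""
    kind_c = current.kind if isinstance(current, OverlapMap) else "suitability"
    kind_f = future.kind if isinstance(future, OverlapMap) else "suitability"
    if kind_c != kind_f:
        raise ValueError(f"kind mismatch: {kind_c} vs {kind_f}")
    gc, gf = current.grid, future.grid
    gc.require_aligned(gf)
    mask = gc.mask & gf.mask
    diff = np.where(mask, gf.values - gc.values, np.nan)
    scen_c = getattr(current, "scenario", "current")
    scen_f = getattr(future, "scenario", "future")
    return ChangeMap(gc.copy_with(diff, mask), kind_c, (scen_c, scen_f))


def fraction_area_increasing(change: ChangeMap, areas: RasterGrid) -> float:
    """Percentage of valid land area where the change is positive."""
    g = change.grid
    g.require_aligned(areas)
    if not g.mask.any():
        raise ValueError("change map has no valid cells")
    total = areas.values[g.mask].sum()
    inc = areas.values[g.mask & (g.values > 0)].sum()
    return float(100.0 * inc / total)


def hotspot_mask(overlap: OverlapMap, areas: RasterGrid,
                 quantile: float = 0.9) -> RasterGrid:
    """Binary mask of cells at or above the area-weighted overlap quantile.

    The default top decile flags the cells jointly suitable for (or jointly
    invadable by) the most species — the operational hotspot definition.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0,1)")
    g = overlap.grid
    g.require_aligned(areas)
    vals = g.values[g.mask]
    w = areas.values[g.mask]
    if vals.size == 0 or vals.min() == vals.max():
        raise ValueError("no quantile contrast: overlap map is constant")
    order = np.argsort(vals)
    cum = np.cumsum(w[order]) / w.sum()
    threshold = vals[order][np.searchsorted(cum, quantile)]
    out = np.where(g.mask, (g.values >= threshold).astype(float), np.nan)
    return g.copy_with(out)
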