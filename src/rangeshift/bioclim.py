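"""The 19 bioclimatic variables (BIO1–BIO19) from monthly climate cubes.

Follows the WorldClim conventions: BIO4 is the population standard deviation
of monthly mean temperature ×100; quarters are any 3 consecutive months with
December–January wraparound; wettest/driest quarters are ranked by total
precipitation and warmest/coldest by mean temperature, ties broken toward
the earliest quarter of the year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid

BIOCLIM_NAMES = tuple(f"BIO{i}" for i in range(1, 20))


@dataclass
class MonthlyClimateCube:
    """12 months of gridded climate: shape (12, nrows, ncols) per variable.

    ``tavg``, ``tmin``, ``tmax`` in °C; ``prec`` in mm/month. ``grid`` supplies
    the common geometry and validity mask.
    """

    tavg: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray
    grid: RasterGrid

    def __post_init__(self) -> None:
        for name in ("tavg", "tmin", "tmax", "prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12, self.grid.nrows, self.grid.ncols):
                raise ValueError(f"{name} must have shape (12, nrows, ncols); "
                                 f"got {arr.shape}")
            setattr(self, name, arr)


def _quarter_stats(monthly: np.ndarray, reduce: str) -> np.ndarray:
    """Rolling 3-month statistic for all 12 wraparound quarters: (12, R, C)."""
    stacked = np.stack(
        [monthly[[q, (q + 1) % 12, (q + 2) % 12]].sum(axis=0) for q in range(12)]
    )
    if reduce == "mean":
        return stacked / 3.0
    return stacked


def _pick(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Per-cell selection along the quarter axis."""
    return np.take_along_axis(values, idx[None], axis=0)[0]


def compute_bioclim(cube: MonthlyClimateCube) -> dict[str, RasterGrid]:
    """Compute BIO1–BIO19 as named RasterGrids on the cube's grid."""
    tavg, tmin, tmax, prec = cube.tavg, cube.tmin, cube.tmax, cube.prec

    bio: dict[str, np.ndarray] = {}
    bio["BIO1"] = tavg.mean(axis=0)
    bio["BIO2"] = (tmax - tmin).mean(axis=0)
    bio["BIO4"] = 100.0 * tavg.std(axis=0)  # population SD, WorldClim scaling
    bio["BIO5"] = tmax.max(axis=0)
    bio["BIO6"] = tmin.min(axis=0)
    bio["BIO7"] = bio["BIO5"] - bio["BIO6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bio["BIO3"] = np.where(bio["BIO7"] != 0, 100.0 * bio["BIO2"] / bio["BIO7"], 0.0)
    bio["BIO12"] = prec.sum(axis=0)
    bio["BIO13"] = prec.max(axis=0)
    bio["BIO14"] = prec.min(axis=0)
    bio["BIO15"] = 100.0 * prec.std(axis=0) / (1.0 + bio["BIO12"] / 12.0)

    tq = _quarter_stats(tavg, "mean")   # quarter mean temperature
    pq = _quarter_stats(prec, "sum")    # quarter precipitation total
    wettest = pq.argmax(axis=0)         # first max → earliest-quarter tie rule
    driest = pq.argmin(axis=0)
    warmest = tq.argmax(axis=0)
    coldest = tq.argmin(axis=0)

    bio["BIO8"] = _pick(tq, wettest)
    bio["BIO9"] = _pick(tq, driest)
    bio["BIO10"] = tq.max(axis=0)
    bio["BIO11"] = tq.min(axis=0)
    bio["BIO16"] = pq.max(axis=0)
    bio["BIO17"] = pq.min(axis=0)
    bio["BIO18"] = _pick(pq, warmest)
    bio["BIO19"] = _pick(pq, coldest)

    g = cube.grid
    return {name: g.copy_with(bio[name]) for name in BIOCLIM_NAMES}
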