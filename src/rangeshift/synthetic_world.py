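"""A virtual study system with known truth.

Generates multi-scenario climate/land-use/terrain rasters and niche-driven
occurrence records so the whole distribution-modelling pipeline can be
exercised — and its niche recovery verified — without any external downloads.
Monthly temperature is a seasonal cycle plus a smooth latitudinal gradient
plus spatially correlated noise; precipitation is a positive log-scaled
field with its own seasonal cycle; land-use fractions are a normalised
composition of correlated fields; occurrences are sampled from a known
logistic niche over the derived predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .bioclim import MonthlyClimateCube
from .grid import RasterGrid
from .maps import SuitabilityMap
from .occurrences import OccurrenceSet
from .predictors import LANDUSE_NAMES, PredictorStack, build_stack

#: relative prior weight of each land-use class (plus unassigned background)
_LANDUSE_WEIGHTS = {"urban": 0.2, "crop": 1.0, "range": 1.0, "secdn": 0.5,
                    "primn": 0.5, "primf": 1.0, "secdf": 0.5, "pastr": 0.8}
_BACKGROUND_WEIGHT = 3.0


@dataclass(frozen=True)
class WorldConfig:
    """Geometry, climate baselines and noise structure of the virtual world.

    The defaults give a 200×100-cell mid-latitude domain (6 arc-min cells)
    with an 8 °C north–south annual-mean temperature span, an 8 °C seasonal
    cycle peaking in July, and ~60 mm/month precipitation — magnitudes a
    temperate study region would show.
    """

    west: float = 0.0
    south: float = 35.0
    east: float = 20.0
    north: float = 45.0
    resolution_arcmin: float = 6.0
    correlation_length: float = 10.0   # cells, e-folding scale of field noise
    temp_south: float = 18.0           # °C annual mean at the southern edge
    temp_lat_gradient: float = -0.8    # °C per degree latitude
    seasonal_amplitude: float = 8.0    # °C, half peak-to-trough annual cycle
    amplitude_variation: float = 0.3   # relative spatial modulation of the cycle
    diurnal_range: float = 8.0         # °C tmax − tmin
    temp_noise_sd: float = 1.5         # °C
    prec_monthly_mean: float = 60.0    # mm
    prec_seasonality: float = 0.5      # relative seasonal amplitude
    prec_noise_sd: float = 0.4         # log-scale
    prec_lon_gradient: float = 0.5     # log-scale west→east trend
    dem_mean: float = 400.0            # m
    dem_relief: float = 300.0          # m
    landuse_contrast: float = 1.0      # log-scale spread of land-use fields
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution_arcmin <= 0:
            raise ValueError("resolution must be positive")
        if self.east <= self.west or self.north <= self.south:
            raise ValueError("degenerate extent")

    @property
    def cellsize(self) -> float:
        return self.resolution_arcmin / 60.0

    @property
    def shape(self) -> tuple[int, int]:
        nrows = round((self.north - self.south) / self.cellsize)
        ncols = round((self.east - self.west) / self.cellsize)
        if nrows < 1 or ncols < 1:
            raise ValueError("extent smaller than one cell")
        return nrows, ncols


@dataclass(frozen=True)
class ScenarioDelta:
    """A future scenario as a perturbation of the current world."""

    label: str
    temp_shift: float | np.ndarray = 0.0      # °C, additive
    prec_factor: float | np.ndarray = 1.0     # multiplicative
    #: {(from_class, to_class): fraction of the source layer moved}
    landuse_transitions: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.prec_factor) <= 0):
            raise ValueError("precipitation factor must be positive")
        if self.label == "current":
            raise ValueError('scenario label "current" is reserved')


@dataclass(frozen=True)
class NicheSpec:
    """Ground-truth logistic niche over named predictors.

    Suitability = logistic(intercept + Σ βᵢ·zᵢ + Σ γᵢ·zᵢ²) with
    zᵢ = (xᵢ − centerᵢ)/scaleᵢ.  Centers/scales default to 0/1.
    """

    species: str
    intercept: float = 0.0
    linear: dict[str, float] = field(default_factory=dict)
    quadratic: dict[str, float] = field(default_factory=dict)
    centers: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)

    @property
    def predictors(self) -> list[str]:
        return sorted(set(self.linear) | set(self.quadratic))


@dataclass
class SyntheticWorld:
    """One scenario's full raster inputs on a common grid."""

    scenario: str
    cube: MonthlyClimateCube
    landuse: dict[str, RasterGrid]
    dem: RasterGrid
    config: WorldConfig

    def __post_init__(self) -> None:
        if np.any(self.cube.tmin > self.cube.tavg + 1e-9) or \
           np.any(self.cube.tavg > self.cube.tmax + 1e-9):
            raise ValueError("tmin ≤ tavg ≤ tmax violated")
        total = np.zeros(self.dem.values.shape)
        for name, layer in self.landuse.items():
            v = layer.values
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise ValueError(f"land-use fraction {name} outside [0,1]")
            total += v
        if np.any(total > 1 + 1e-9):
            raise ValueError("land-use fractions sum to more than 1")
        self._stack_cache: PredictorStack | None = None

    @property
    def grid(self) -> RasterGrid:
        return self.dem

    def predictor_stack(self) -> PredictorStack:
        if self._stack_cache is None:
            self._stack_cache = build_stack(self.cube, self.landuse, self.dem,
                                            scenario=self.scenario)
        return self._stack_cache


def demo_niches() -> list[NicheSpec]:
    """Two reference virtual species on the default world.

    ``waspA`` occupies a restricted climatic envelope — a band around a
    13 °C annual-mean optimum, wetter-is-better, mid-elevations — giving a
    low-prevalence (~10% of cells) species like a typical invader.
    ``waspB`` is warm-limited: suitability rises with annual mean
    temperature past a mid-domain isotherm, so warming shifts its range
    boundary poleward.
    """
    wasp_a = NicheSpec(
        "waspA", intercept=3.0,
        linear={"BIO12": 1.5},
        quadratic={"BIO1": -12.0, "elevation": -3.0},
        centers={"BIO1": 13.0, "BIO12": 700.0, "elevation": 400.0},
        scales={"BIO1": 1.2, "BIO12": 400.0, "elevation": 500.0},
    )
    wasp_b = NicheSpec(
        "waspB", intercept=0.0,
        linear={"BIO1": 2.5, "BIO12": 0.5},
        quadratic={"elevation": -1.0},
        centers={"BIO1": 17.0, "BIO12": 700.0, "elevation": 400.0},
        scales={"BIO1": 0.8, "BIO12": 400.0, "elevation": 600.0},
    )
    return [wasp_a, wasp_b]


def demo_scenarios() -> list[ScenarioDelta]:
    """Four future deltas: two emission pathways × two GCM-like variants.

    The optimistic pathway warms ~+1.5–1.8 °C with slightly wetter
    conditions; the pessimistic one ~+3.7–4.0 °C and drier — end-of-century
    magnitudes for the respective pathways.
    """
    return [
        ScenarioDelta("F126", temp_shift=1.8, prec_factor=1.03),
        ScenarioDelta("F585", temp_shift=3.7, prec_factor=0.95),
        ScenarioDelta("M126", temp_shift=1.5, prec_factor=1.05),
        ScenarioDelta("M585", temp_shift=4.0, prec_factor=0.92),
    ]


def _correlated_field(rng: np.random.Generator, shape: tuple[int, int],
                      length: float) -> np.ndarray:
    """Unit-variance Gaussian random field; correlation e-folds at ``length``
    cells (Gaussian-filtered white noise, σ_filter = length/2)."""
    white = rng.standard_normal(shape)
    if length <= 0:
        return white
    f = gaussian_filter(white, sigma=length / 2.0, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the current-scenario world; bit-for-bit reproducible by seed."""
    nrows, ncols = config.shape
    shape = (nrows, ncols)
    template = RasterGrid(np.zeros(shape), config.west, config.north, config.cellsize)
    rng = np.random.default_rng(config.seed)
    L = config.correlation_length

    f_temp = _correlated_field(rng, shape, L)
    f_amp = _correlated_field(rng, shape, L)
    f_spread = _correlated_field(rng, shape, L)
    f_prec = _correlated_field(rng, shape, L)
    f_dem = _correlated_field(rng, shape, L)
    f_landuse = [_correlated_field(rng, shape, L) for _ in range(len(LANDUSE_NAMES) + 1)]

    lat = template.lat_grid()
    lon = template.lon_grid()

    annual_mean = (config.temp_south
                   + config.temp_lat_gradient * (lat - config.south)
                   + config.temp_noise_sd * f_temp)
    amp = config.seasonal_amplitude * (1.0 + config.amplitude_variation * f_amp)
    months = np.arange(12)
    cycle = np.cos(2 * np.pi * (months - 6) / 12.0)  # peak in July (m=6)
    tavg = annual_mean[None] + amp[None] * cycle[:, None, None]

    spread = config.diurnal_range * np.clip(1.0 + 0.2 * f_spread, 0.2, None)
    tmin = tavg - spread[None] / 2.0
    tmax = tavg + spread[None] / 2.0

    lon_mid = (config.west + config.east) / 2.0
    lon_half = (config.east - config.west) / 2.0
    log_scale = config.prec_noise_sd * f_prec \
        + config.prec_lon_gradient * (lon - lon_mid) / lon_half
    seasonal = np.clip(1.0 + config.prec_seasonality * cycle, 0.0, None)
    prec = config.prec_monthly_mean * seasonal[:, None, None] * np.exp(log_scale)[None]

    cube = MonthlyClimateCube(tavg=tavg, tmin=tmin, tmax=tmax, prec=prec,
                              grid=template)

    weights = [np.exp(config.landuse_contrast * f) *
               _LANDUSE_WEIGHTS[name] for name, f
               in zip(LANDUSE_NAMES, f_landuse)]
    background = np.exp(config.landuse_contrast * f_landuse[-1]) * _BACKGROUND_WEIGHT
    denom = background + sum(weights)
    landuse = {name: template.copy_with(w / denom)
               for name, w in zip(LANDUSE_NAMES, weights)}

    dem_values = np.clip(config.dem_mean + config.dem_relief * f_dem, 0.0, None)
    dem = template.copy_with(dem_values)

    return SyntheticWorld("current", cube, landuse, dem, config)


def apply_scenario(world: SyntheticWorld, delta: ScenarioDelta) -> SyntheticWorld:
    """Derive a future-scenario world: shift temperature, scale precipitation,
    move land-use fractions between classes.  The grid is unchanged."""
    cube = world.cube
    new_cube = MonthlyClimateCube(
        tavg=cube.tavg + delta.temp_shift,
        tmin=cube.tmin + delta.temp_shift,
        tmax=cube.tmax + delta.temp_shift,
        prec=cube.prec * delta.prec_factor,
        grid=cube.grid,
    )
    landuse = {name: layer.copy_with(layer.values.copy())
               for name, layer in world.landuse.items()}
    for (src, dst), frac in delta.landuse_transitions.items():
        if not 0 <= frac <= 1:
            raise ValueError("transition fraction must be in [0,1]")
        moved = landuse[src].values * frac
        landuse[src].values -= moved
        landuse[dst].values += moved
    return SyntheticWorld(delta.label, new_cube, landuse, world.dem, world.config)


def true_suitability(world: SyntheticWorld, niche: NicheSpec) -> SuitabilityMap:
    """Ground-truth suitability map of a niche over the world's predictors."""
    stack = world.predictor_stack()
    missing = [p for p in niche.predictors if p not in stack.layers]
    if missing:
        raise ValueError(f"niche references unknown predictors: {missing}")
    eta = np.full(world.grid.values.shape, niche.intercept, dtype=float)
    for name in niche.predictors:
        x = stack.layers[name].values
        z = (x - niche.centers.get(name, 0.0)) / niche.scales.get(name, 1.0)
        eta += niche.linear.get(name, 0.0) * z
        eta += niche.quadratic.get(name, 0.0) * z**2
    suit = expit(eta)
    grid = world.grid.copy_with(suit, stack.valid_mask())
    return SuitabilityMap(grid=grid, species=niche.species, scenario=world.scenario)


def sample_occurrences(truth: SuitabilityMap, n: int, seed: int,
                       uncertainty_range_km: tuple[float, float] = (0.0, 8.0),
                       effort: RasterGrid | None = None) -> OccurrenceSet:
    """Draw presence records with cell probability ∝ suitability.

    Coordinates are jittered uniformly within the source cell; each record
    carries a coordinate uncertainty drawn uniformly from the given range.
    An optional multiplicative effort layer models sampling bias (off by
    default).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    g = truth.grid
    weights = np.where(g.mask, g.values, 0.0).astype(float)
    if effort is not None:
        g.require_aligned(effort)
        weights = weights * np.where(effort.mask, effort.values, 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no sampleable mass: suitability is zero everywhere")
    rng = np.random.default_rng(seed)
    flat = rng.choice(weights.size, size=n, p=weights.ravel() / total)
    row, col = np.unravel_index(flat, weights.shape)
    lon = g.west + (col + rng.uniform(size=n)) * g.cellsize
    lat = g.north - (row + rng.uniform(size=n)) * g.cellsize
    lo, hi = uncertainty_range_km
    unc = rng.uniform(lo, hi, size=n)
    df = pd.DataFrame({"lon": lon, "lat": lat, "uncertainty_km": unc})
    return OccurrenceSet(truth.species, df, provenance="raw")
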