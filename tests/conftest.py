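import numpy as np
import pytest

from rangeshift.bioclim import MonthlyClimateCube
from rangeshift.grid import RasterGrid
from rangeshift.synthetic_world import WorldConfig, generate_world


def make_grid(values, west=0.0, north=1.0, cellsize=0.1, mask=None):
    return RasterGrid(np.asarray(values, dtype=float), west, north, cellsize,
                      mask)


def random_cube(seed=0, shape=(4, 3), grid=None):
    """Small random but physical monthly climate cube for oracle checks."""
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = make_grid(np.zeros(shape))
    tavg = rng.uniform(-5, 25, size=(12, *shape))
    half = rng.uniform(1, 6, size=(12, *shape))
    cube = MonthlyClimateCube(tavg=tavg, tmin=tavg - half, tmax=tavg + half,
                              prec=rng.uniform(0, 300, size=(12, *shape)),
                              grid=grid)
    return cube


@pytest.fixture(scope="session")
def small_world():
    """A 60×30-cell world, fast enough for per-module tests."""
    cfg = WorldConfig(west=0.0, south=38.0, east=6.0, north=41.0, seed=42)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_stack(small_world):
    return small_world.predictor_stack()
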