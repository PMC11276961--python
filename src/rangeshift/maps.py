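"""Suitability and potential-range map containers (grid + labels)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid


@dataclass
class SuitabilityMap:
    """Continuous habitat suitability in [0,1] for one species × scenario."""

    grid: RasterGrid
    species: str
    scenario: str

    def __post_init__(self) -> None:
        v = self.grid.values[self.grid.mask]
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0,1]")


@dataclass
class RangeMap:
    """Binary potential range (1 = inside) for one species × scenario."""

    grid: RasterGrid
    species: str
    scenario: str
    threshold: float

    def __post_init__(self) -> None:
        v = self.grid.values[self.grid.mask]
        if v.size and not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("range map values must be 0 or 1")

    def inside(self) -> np.ndarray:
        return self.grid.mask & (self.grid.values == 1.0)
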