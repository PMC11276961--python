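"""Occurrence record handling: cleaning and spatial thinning.

Mirrors the standard presence-data workflow for distribution modelling:
records with coarse coordinate uncertainty (> 5 km by default) are dropped,
then the remainder is spatially thinned so that no two retained records fall
within a minimum great-circle distance of each other, which damps sampling-
effort clustering before pseudo-absence modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import EARTH_RADIUS_KM

#: Darwin-Core-style aliases accepted on CSV input (metres converted to km).
_COLUMN_ALIASES = {
    "decimallongitude": "lon",
    "decimallatitude": "lat",
    "coordinateuncertaintyinmeters": "uncertainty_m",
}


@dataclass
class OccurrenceSet:
    """Presence records for one species.

    ``records`` has columns lon, lat, uncertainty_km (NaN = unknown).
    """

    species: str
    records: pd.DataFrame
    provenance: str = "raw"

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True).copy()
        if "uncertainty_km" not in df.columns:
            df["uncertainty_km"] = np.nan
        if ((df.lon < -180) | (df.lon > 180)).any():
            raise ValueError("longitude out of [-180, 180]")
        if ((df.lat < -90) | (df.lat > 90)).any():
            raise ValueError("latitude out of [-90, 90]")
        self.records = df[["lon", "lat", "uncertainty_km"]]

    def __len__(self) -> int:
        return len(self.records)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_csv(cls, path: str | Path, species: str | None = None) -> "OccurrenceSet":
        df = pd.read_csv(path)
        df.columns = [c.strip() for c in df.columns]
        renames = {c: _COLUMN_ALIASES[c.lower()] for c in df.columns
                   if c.lower() in _COLUMN_ALIASES}
        df = df.rename(columns=renames)
        if "uncertainty_m" in df.columns and "uncertainty_km" not in df.columns:
            df["uncertainty_km"] = df.pop("uncertainty_m") / 1000.0
        if species is None:
            if "species" not in df.columns or df.species.nunique() != 1:
                raise ValueError("species must be given or be a single-valued column")
            species = str(df.species.iloc[0])
        return cls(species, df)

    def write_csv(self, path: str | Path) -> None:
        out = self.records.copy()
        out.insert(0, "species", self.species)
        out.to_csv(path, index=False)


def filter_uncertainty(occ: OccurrenceSet, max_uncertainty_km: float = 5.0,
                       keep_missing: bool = True) -> OccurrenceSet:
    """Drop records whose coordinate uncertainty exceeds the cutoff.

    Records with missing uncertainty are retained by default: absence of
    metadata is not evidence of a coordinate error.
    """
    unc = occ.records.uncertainty_km
    keep = unc <= max_uncertainty_km
    if keep_missing:
        keep |= unc.isna()
    return OccurrenceSet(occ.species, occ.records[keep], provenance="filtered")


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine distance in km on a sphere of radius 6371 km (vectorised)."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dphi = lat2 - lat1
    dlam = lon2 - lon1
    a = np.sin(dphi / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def thin_spatial(occ: OccurrenceSet, diameter_km: float = 5.0,
                 seed: int = 0) -> OccurrenceSet:
    """Randomised-greedy spatial thinning to a minimum pairwise distance.

    Records are visited in a seed-shuffled order and accepted iff they lie at
    least ``diameter_km`` from every already-accepted record.  The result is
    maximal (every rejected record is within the diameter of an accepted
    one) and deterministic given the seed.
    """
    df = occ.records
    n = len(df)
    if n <= 1:
        return OccurrenceSet(occ.species, df, provenance="thinned")
    order = np.random.default_rng(seed).permutation(n)
    lon = df.lon.to_numpy()
    lat = df.lat.to_numpy()
    accepted: list[int] = []
    for i in order:
        if not accepted:
            accepted.append(i)
            continue
        d = great_circle_km(lon[i], lat[i], lon[accepted], lat[accepted])
        if np.all(d >= diameter_km):
            accepted.append(i)
    keep = sorted(accepted)
    return OccurrenceSet(occ.species, df.iloc[keep], provenance="thinned")
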