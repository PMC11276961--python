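"""Predictor stacks and the collinearity / jackknife selection procedure.

A :class:`PredictorStack` bundles the 30 candidate predictors per scenario —
19 bioclimatic variables, 8 land-use fractions, and 3 terrain layers — on one
grid.  Selection proceeds in two steps, mirroring common SDM practice:

1. variable importance of every candidate from a fast preliminary model via
   the jackknife (leave-one-predictor-out drop in cross-validated AUC), and
2. a |r| > 0.7 Pearson collinearity screen that, within each offending pair,
   retains the member with the higher jackknife importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .bioclim import MonthlyClimateCube, compute_bioclim
from .grid import RasterGrid
from .metrics import auc
from .terrain import compute_terrain

LANDUSE_NAMES = ("urban", "crop", "range", "secdn", "primn", "primf", "secdf", "pastr")
TERRAIN_NAMES = ("elevation", "slope", "aspect")


@dataclass
class PredictorStack:
    """Named, grid-aligned predictor layers for one scenario."""

    scenario: str
    layers: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        for g in grids[1:]:
            grids[0].require_aligned(g)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def valid_mask(self) -> np.ndarray:
        """Cells where every layer holds data."""
        mask = np.ones(self.grid.values.shape, dtype=bool)
        for layer in self.layers.values():
            mask &= layer.mask
        return mask

    def table(self, names: list[str] | None = None,
              cells: np.ndarray | None = None) -> pd.DataFrame:
        """Predictor values as a (cells × predictors) table.

        ``cells`` is a boolean grid mask; defaults to all jointly valid cells.
        """
        names = names or self.names
        if cells is None:
            cells = self.valid_mask()
        return pd.DataFrame({n: self.layers[n].values[cells] for n in names})

    def extract(self, lon, lat, names: list[str] | None = None) -> pd.DataFrame:
        """Predictor values at point locations (containing-cell lookup)."""
        names = names or self.names
        row, col = self.grid.cell_index(lon, lat)
        row = np.clip(row, 0, self.grid.nrows - 1)
        col = np.clip(col, 0, self.grid.ncols - 1)
        return pd.DataFrame({n: self.layers[n].values[row, col] for n in names})

    def subset(self, names: list[str]) -> "PredictorStack":
        return PredictorStack(self.scenario, {n: self.layers[n] for n in names})


def build_stack(cube: MonthlyClimateCube, landuse: dict[str, RasterGrid],
                dem: RasterGrid, scenario: str = "current") -> PredictorStack:
    """Assemble the full 30-layer stack from raw inputs."""
    layers = dict(compute_bioclim(cube))
    for name in LANDUSE_NAMES:
        layers[name] = landuse[name]
    slope, aspect = compute_terrain(dem)
    layers["elevation"] = dem
    layers["slope"] = slope
    layers["aspect"] = aspect
    return PredictorStack(scenario, layers)


def pearson_matrix(stack: PredictorStack, cells: np.ndarray | None = None,
                   names: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlations over the sampled cells.

    Zero-variance predictors get correlation 0 (flagged with a warning);
    the diagonal is exactly 1.
    """
    tbl = stack.table(names=names, cells=cells)
    if len(tbl) < 3:
        raise ValueError("need at least 3 cells for correlation")
    if tbl.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    sd = tbl.std(ddof=0)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        warnings.warn(f"zero-variance predictors, correlations set to 0: {degenerate}")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(tbl.to_numpy(), rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=tbl.columns, columns=tbl.columns)


def _cv_auc(X: np.ndarray, y: np.ndarray, folds: list[tuple]) -> float:
    """Cross-validated AUC of a regularized logistic model on fixed folds.

    Each predictor enters as x + x² (no interactions), the customary GLM
    formula for niche responses, so band-shaped responses register.
    """
    Xa = np.hstack([X, X**2])
    scores = []
    for tr, te in folds:
        model = make_pipeline(StandardScaler(),
                              LogisticRegression(max_iter=2000, C=1.0))
        model.fit(Xa[tr], y[tr])
        s = model.predict_proba(Xa[te])[:, 1]
        scores.append(auc(s[y[te] == 1], s[y[te] == 0]))
    return float(np.mean(scores))


def jackknife_importance(stack: PredictorStack, presences: pd.DataFrame,
                         pseudo_absences: pd.DataFrame, n_folds: int = 4,
                         seed: int = 0) -> pd.Series:
    """Leave-one-predictor-out importance from a preliminary model.

    importance(p) = CV-AUC(all predictors) − CV-AUC(all but p), floored at 0,
    with the same stratified folds reused for every predictor so differences
    reflect the predictor, not fold noise.
    """
    names = [c for c in presences.columns]
    if len(presences) < 10:
        raise ValueError("need at least 10 presences for the preliminary model")
    X = pd.concat([presences, pseudo_absences], ignore_index=True)[names].to_numpy()
    y = np.concatenate([np.ones(len(presences)), np.zeros(len(pseudo_absences))])
    if min(len(presences), len(pseudo_absences)) < n_folds:
        raise ValueError("fewer records in a class than CV folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    full = _cv_auc(X, y, folds)
    imp = {}
    for j, name in enumerate(names):
        Xj = np.delete(X, j, axis=1)
        imp[name] = max(0.0, full - _cv_auc(Xj, y, folds))
    return pd.Series(imp, name="importance")


_EXACT_COMPONENT_LIMIT = 15


def _greedy_drop(names: list[str], corr: pd.DataFrame, importance: pd.Series,
                 threshold: float) -> set[str]:
    """Descending-|r| greedy: repeatedly drop the lower-importance member of
    the worst remaining conflict (ties drop the later-sorting name)."""
    retained = set(names)
    ordered = sorted(names)
    while True:
        worst, worst_pair = threshold, None
        for i, a in enumerate(ordered):
            if a not in retained:
                continue
            for b in ordered[i + 1:]:
                if b not in retained:
                    continue
                r = abs(corr.loc[a, b])
                if r > worst:
                    worst, worst_pair = r, (a, b)
        if worst_pair is None:
            return retained
        a, b = worst_pair
        ia, ib = importance[a], importance[b]
        drop = b if (ia > ib or (ia == ib and a < b)) else a
        retained.discard(drop)


def _exact_subset(names: list[str], corr: pd.DataFrame, importance: pd.Series,
                  threshold: float) -> set[str]:
    """Feasible subset maximising summed importance (exhaustive).

    Ties prefer the larger subset, then the lexicographically earliest name
    tuple, so the choice is deterministic and order-invariant.
    """
    ordered = sorted(names)
    n = len(ordered)
    best_key, best_subset = (-1.0, -1), []
    # ascending bit order + strict improvement → deterministic tie-break
    for bits in range(2**n):
        subset = [ordered[i] for i in range(n) if bits >> i & 1]
        ok = all(abs(corr.loc[a, b]) <= threshold
                 for i, a in enumerate(subset) for b in subset[i + 1:])
        if not ok:
            continue
        key = (sum(importance[s] for s in subset), len(subset))
        if key > best_key:
            best_key, best_subset = key, subset
    return set(best_subset)


def select_predictors(corr: pd.DataFrame, importance: pd.Series,
                      threshold: float = 0.7) -> list[str]:
    """Resolve collinearity: within every group of conflicting predictors
    (|r| > threshold), keep the subset with the highest total importance.

    Conflicts are independent across connected components of the |r| >
    threshold graph, so each component is solved exactly (exhaustively) when
    small; very large components fall back to a deterministic descending-|r|
    greedy that drops the lower-importance member of the worst pair.  Every
    retained pair satisfies |r| ≤ threshold and the result is invariant to
    the input ordering of predictors.
    """
    names = list(corr.index)
    if set(importance.index) < set(names):
        raise ValueError("importance must cover all predictors in corr")
    # connected components of the conflict graph
    adj = {a: {b for b in names if b != a
               and abs(corr.loc[a, b]) > threshold} for a in names}
    seen: set[str] = set()
    retained: set[str] = set()
    for start in sorted(names):
        if start in seen:
            continue
        comp, frontier = {start}, [start]
        while frontier:
            node = frontier.pop()
            for nb in adj[node]:
                if nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        seen |= comp
        if len(comp) == 1:
            retained |= comp
        elif len(comp) <= _EXACT_COMPONENT_LIMIT:
            retained |= _exact_subset(sorted(comp), corr, importance, threshold)
        else:
            retained |= _greedy_drop(sorted(comp), corr, importance, threshold)
    return [n for n in names if n in retained]
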