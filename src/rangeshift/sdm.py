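"""Gated ensemble species distribution models.

Per species the workflow is: sample pseudo-absences (five independently
seeded repetitions), split 70/30 five times, fit every rostered algorithm on
each training part, evaluate AUC and TSS on the held-out part (TSS at the
MSS threshold of the test scores), and admit a candidate into the ensemble
iff TSS > 0.6 OR AUC > 0.8.  The ensemble prediction is the TSS-weighted
mean of the admitted members — committee averaging in the biomod2 style.

Native algorithms: a strict rectilinear surface range envelope (SRE), a
regularized logistic model (GLM), a random forest (RF), and gradient
boosting (GBM).  Further algorithms can be registered through
``ALGORITHMS``; the gating/ensembling surface treats all of them alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .maps import SuitabilityMap
from .metrics import EvalMetrics, auc, mss_threshold, tss_at_threshold
from .occurrences import OccurrenceSet
from .predictors import PredictorStack

__all__ = [
    "TrainingSet", "EnsembleMember", "EnsembleModel", "ALGORITHMS",
    "sample_pseudo_absences", "split_cv", "fit_algorithm", "gate_models",
    "ensemble_predict", "auc", "tss_at_threshold", "EvalMetrics",
]


@dataclass
class TrainingSet:
    """Presence and pseudo-absence predictor tables for one PA repetition."""

    species: str
    repetition: int
    presence: pd.DataFrame
    absence: pd.DataFrame
    #: (lon, lat) arrays of the absence cells, kept for site-based scoring
    absence_coords: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(self.presence) < 1 or len(self.absence) < 1:
            raise ValueError("need at least one presence and one absence")
        if self.presence.isna().any().any() or self.absence.isna().any().any():
            raise ValueError("NaN predictor values in training data")

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        X = pd.concat([self.presence, self.absence], ignore_index=True).to_numpy()
        y = np.concatenate([np.ones(len(self.presence)), np.zeros(len(self.absence))])
        return X, y


def sample_pseudo_absences(stack: PredictorStack, occ: OccurrenceSet,
                           repetition: int, seed: int,
                           n_pa: int | None = None) -> TrainingSet:
    """Draw pseudo-absences uniformly from valid non-presence cells.

    The PA count follows the max(1000, n_occurrences) rule unless overridden.
    """
    n_occ = len(occ)
    if n_pa is None:
        n_pa = max(1000, n_occ)
    valid = stack.valid_mask()
    row, col = stack.grid.cell_index(occ.records.lon.to_numpy(),
                                     occ.records.lat.to_numpy())
    presence_cells = np.zeros(valid.shape, dtype=bool)
    inb = (row >= 0) & (row < valid.shape[0]) & (col >= 0) & (col < valid.shape[1])
    presence_cells[row[inb], col[inb]] = True
    candidates = np.flatnonzero(valid & ~presence_cells)
    if candidates.size < n_pa:
        raise ValueError(f"only {candidates.size} candidate cells for {n_pa} PAs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_pa, replace=False)
    r, c = np.unravel_index(chosen, valid.shape)
    lons = stack.grid.lons()[c]
    lats = stack.grid.lats()[r]
    X_pres = stack.extract(occ.records.lon.to_numpy(), occ.records.lat.to_numpy())
    X_abs = stack.extract(lons, lats)
    return TrainingSet(occ.species, repetition, X_pres.dropna(), X_abs.dropna(),
                       absence_coords=(lons, lats))


def split_cv(train: TrainingSet, fraction: float = 0.7, repetition: int = 0,
             seed: int = 0) -> tuple[TrainingSet, TrainingSet]:
    """Stratified random 70/30 split of presences and pseudo-absences."""
    if len(train.presence) + len(train.absence) < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(seed)

    def _split(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = rng.permutation(len(df))
        k = max(1, min(len(df) - 1, int(round(fraction * len(df)))))
        return df.iloc[np.sort(idx[:k])], df.iloc[np.sort(idx[k:])]

    p_tr, p_te = _split(train.presence)
    a_tr, a_te = _split(train.absence)
    return (TrainingSet(train.species, repetition, p_tr, a_tr),
            TrainingSet(train.species, repetition, p_te, a_te))


# -- algorithms -------------------------------------------------------------

class SREModel:
    """Strict BIOCLIM-style rectilinear envelope: 1 inside the presence
    min/max box on every predictor, else 0."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SREModel":
        pres = X[y == 1]
        if pres.shape[0] == 0:
            raise ValueError("no presences to build envelope")
        self.lo_ = pres.min(axis=0)
        self.hi_ = pres.max(axis=0)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        inside = np.all((X >= self.lo_) & (X <= self.hi_), axis=1)
        return inside.astype(float)


class SklearnScoreModel:
    """Adapter exposing predict_score() over a sklearn classifier."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate fit: one class only")
        self.estimator.fit(X, y)
        return self

    def predict_score(self, X) -> np.ndarray:
        return self.estimator.predict_proba(X)[:, 1]


def _make_glm(seed: int) -> SklearnScoreModel:
    # linear + quadratic terms, the customary GLM formula for niche models
    return SklearnScoreModel(make_pipeline(
        StandardScaler(), PolynomialFeatures(degree=2, include_bias=False),
        LogisticRegression(max_iter=2000, C=1.0)))


def _make_rf(seed: int) -> SklearnScoreModel:
    return SklearnScoreModel(RandomForestClassifier(
        n_estimators=100, min_samples_leaf=2, random_state=seed, n_jobs=1))


def _make_gbm(seed: int) -> SklearnScoreModel:
    return SklearnScoreModel(GradientBoostingClassifier(random_state=seed))


ALGORITHMS = {
    "SRE": lambda seed: SREModel(),
    "GLM": _make_glm,
    "RF": _make_rf,
    "GBM": _make_gbm,
}


def fit_algorithm(algorithm: str, train: TrainingSet, seed: int = 0):
    """Fit one rostered algorithm; returns a model with predict_score()."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; "
                         f"roster: {sorted(ALGORITHMS)}")
    X, y = train.xy()
    return ALGORITHMS[algorithm](seed).fit(X, y)


# -- gating and ensembling --------------------------------------------------

@dataclass
class EnsembleMember:
    algorithm: str
    pa_repetition: int
    cv_repetition: int
    model: object
    metrics: EvalMetrics
    included: bool = False
    weight: float = 0.0


@dataclass
class EnsembleModel:
    species: str
    predictor_names: list[str]
    members: list[EnsembleMember] = field(default_factory=list)

    @property
    def included(self) -> list[EnsembleMember]:
        return [m for m in self.members if m.included]


def gate_models(members: list[EnsembleMember], species: str,
                predictor_names: list[str], tss_gate: float = 0.6,
                auc_gate: float = 0.8) -> EnsembleModel:
    """Admit members with TSS > gate OR AUC > gate; weight by TSS, normalised.

    If every admitted member has non-positive TSS (possible only through the
    AUC branch), weights fall back to equal.
    """
    if not members:
        raise ValueError("no candidate members")
    for m in members:
        m.included = (m.metrics.tss > tss_gate) or (m.metrics.auc > auc_gate)
        m.weight = 0.0
    inc = [m for m in members if m.included]
    if not inc:
        raise ValueError("ensemble empty: no member passed the TSS/AUC gate")
    weights = np.array([max(m.metrics.tss, 0.0) for m in inc])
    if weights.sum() == 0:
        weights = np.ones(len(inc))
    weights /= weights.sum()
    for m, w in zip(inc, weights):
        m.weight = float(w)
    return EnsembleModel(species, list(predictor_names), members)


def evaluate_candidate(model, test: TrainingSet) -> EvalMetrics:
    """Held-out AUC and TSS (at the MSS threshold of the test scores)."""
    sp = model.predict_score(test.presence.to_numpy())
    sa = model.predict_score(test.absence.to_numpy())
    try:
        thr = mss_threshold(sp, sa)
    except ValueError:  # degenerate scores: fall back to 0.5
        thr = 0.5
    return tss_at_threshold(sp, sa, thr)


def ensemble_predict(ensemble: EnsembleModel, stack: PredictorStack) -> SuitabilityMap:
    """TSS-weighted mean suitability of the included members over the stack."""
    if not ensemble.included:
        raise ValueError("ensemble has no included members")
    missing = [n for n in ensemble.predictor_names if n not in stack.layers]
    if missing:
        raise ValueError(f"stack is missing predictor layers: {missing}")
    sub = stack.subset(ensemble.predictor_names)
    valid = sub.valid_mask()
    X = sub.table(cells=valid).to_numpy()
    total = np.zeros(X.shape[0])
    for m in ensemble.included:
        total += m.weight * m.model.predict_score(X)
    out = np.full(valid.shape, np.nan)
    out[valid] = np.clip(total, 0.0, 1.0)
    grid = stack.grid.copy_with(out, valid)
    return SuitabilityMap(grid=grid, species=ensemble.species,
                          scenario=stack.scenario)


def build_ensemble(stack: PredictorStack, occ: OccurrenceSet,
                   predictor_names: list[str], seed: int,
                   n_pa_repetitions: int = 5, n_cv_repetitions: int = 5,
                   cv_fraction: float = 0.7, algorithms=("SRE", "GLM", "RF", "GBM"),
                   tss_gate: float = 0.6, auc_gate: float = 0.8,
                   n_pa: int | None = None) -> tuple[EnsembleModel, pd.DataFrame]:
    """Full per-species ensemble: PA reps × CV reps × algorithms, gated.

    Returns the ensemble and an evaluation table (one row per candidate).
    """
    ss = np.random.SeedSequence(seed)
    n_cells = n_pa_repetitions * n_cv_repetitions
    pa_seeds, cv_seeds, fit_seeds = (
        s.generate_state(n_cells).reshape(n_pa_repetitions, n_cv_repetitions)
        % (2**31)
        for s in ss.spawn(3))
    sub = stack.subset(predictor_names)
    candidates: list[EnsembleMember] = []
    rows = []
    for pa_rep in range(n_pa_repetitions):
        tset = sample_pseudo_absences(sub, occ, pa_rep,
                                      int(pa_seeds[pa_rep, 0]), n_pa=n_pa)
        for cv_rep in range(n_cv_repetitions):
            tr, te = split_cv(tset, cv_fraction, cv_rep,
                              int(cv_seeds[pa_rep, cv_rep]))
            for algo in algorithms:
                try:
                    model = fit_algorithm(algo, tr,
                                          seed=int(fit_seeds[pa_rep, cv_rep]))
                    metrics = evaluate_candidate(model, te)
                except ValueError:
                    continue  # singular fit: candidate dropped
                candidates.append(EnsembleMember(algo, pa_rep, cv_rep, model,
                                                 metrics))
                rows.append({"species": occ.species, "algorithm": algo,
                             "pa_repetition": pa_rep, "cv_repetition": cv_rep,
                             "auc": metrics.auc, "tss": metrics.tss})
    ensemble = gate_models(candidates, occ.species, predictor_names,
                           tss_gate, auc_gate)
    table = pd.DataFrame(rows)
    table["included"] = [m.included for m in candidates]
    return ensemble, table
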