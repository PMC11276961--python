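"""Discrimination metrics for presence/absence scores: AUC, TSS, MSS.

AUC is the rank-sum (Mann–Whitney) statistic with ties counted 0.5; TSS is
sensitivity + specificity − 1 at a stated threshold; the MSS threshold is
the cut-off maximising sensitivity + specificity, the standard rule for
binarizing habitat suitability into a potential range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class EvalMetrics:
    auc: float
    tss: float
    sensitivity: float
    specificity: float
    threshold: float


def auc(scores_presence, scores_absence) -> float:
    """Probability a presence outscores an absence (ties count 1/2)."""
    p = np.asarray(scores_presence, dtype=float)
    a = np.asarray(scores_absence, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, a]))
    rank_sum_p = ranks[: p.size].sum()
    return float((rank_sum_p - p.size * (p.size + 1) / 2) / (p.size * a.size))


def tss_at_threshold(scores_presence, scores_absence, threshold: float) -> EvalMetrics:
    """TSS and its components at a threshold: presence iff score ≥ threshold."""
    p = np.asarray(scores_presence, dtype=float)
    a = np.asarray(scores_absence, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score sets must be non-empty")
    sens = float(np.mean(p >= threshold))
    spec = float(np.mean(a < threshold))
    return EvalMetrics(auc=auc(p, a), tss=sens + spec - 1.0,
                       sensitivity=sens, specificity=spec, threshold=float(threshold))


def mss_threshold(scores_presence, scores_absence) -> float:
    """Maximum sensitivity–specificity sum threshold.

    Candidates are the midpoints between consecutive sorted unique scores
    (pooled over both sets), a finite set that realises every achievable
    confusion table; ties are broken toward the lower threshold, favouring
    sensitivity.
    """
    p = np.asarray(scores_presence, dtype=float)
    a = np.asarray(scores_absence, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score sets must be non-empty")
    uniq = np.unique(np.concatenate([p, a]))
    if uniq.size < 2:
        raise ValueError("degenerate scores: all values identical")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    sums = [np.mean(p >= t) + np.mean(a < t) for t in candidates]
    return float(candidates[int(np.argmax(sums))])  # argmax → lowest on ties
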