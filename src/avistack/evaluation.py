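"""Discrimination metrics for presence-background models: AUC, TSS, bands.

AUC here is presence-versus-background: the probability that a randomly drawn
presence scores higher than a randomly drawn background cell, with ties
counting one half (the rank-sum formulation). TSS = sensitivity +
specificity - 1 is threshold-dependent; by default it is reported at the
threshold maximizing sensitivity + specificity. Qualitative AUC bands follow
the Swets scale: excellent (0.9-1.0], good (0.8-0.9], fair (0.7-0.8],
poor (0.6-0.7], fail at or below 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["EvaluationResult", "auc", "tss_at_threshold", "maxsss_threshold", "auc_band"]


@dataclass(frozen=True)
class EvaluationResult:
    auc: float
    tss: float
    sensitivity: float
    specificity: float
    threshold: float
    band: str


def auc(presence_scores, background_scores) -> float:
    """Rank-sum AUC: P(presence score > background score) + 0.5 P(tie)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    rank_sum = ranks[: p.size].sum()
    return float((rank_sum - p.size * (p.size + 1) / 2.0) / (p.size * b.size))


def _sens_spec(p: np.ndarray, b: np.ndarray, threshold: float) -> tuple[float, float]:
    sens = float(np.mean(p >= threshold))
    spec = float(np.mean(b < threshold))
    return sens, spec


def tss_at_threshold(presence_scores, background_scores, threshold: float) -> EvaluationResult:
    """Sensitivity, specificity and TSS with the rule score >= threshold => present."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    sens, spec = _sens_spec(p, b, threshold)
    a = auc(p, b)
    return EvaluationResult(
        auc=a,
        tss=sens + spec - 1.0,
        sensitivity=sens,
        specificity=spec,
        threshold=float(threshold),
        band=auc_band(a),
    )


def maxsss_threshold(presence_scores, background_scores) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the midpoints between consecutive distinct observed scores
    plus the extremes; among maximizers the lowest threshold is returned.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    scores = np.unique(np.concatenate([p, b]))
    if scores.size == 1:
        return float(scores[0])
    mids = (scores[:-1] + scores[1:]) / 2.0
    candidates = np.concatenate([[scores[0]], mids, [scores[-1]]])
    best_t, best_ss = None, -np.inf
    for t in candidates:
        sens, spec = _sens_spec(p, b, t)
        ss = sens + spec
        if ss > best_ss + 1e-12:
            best_ss, best_t = ss, float(t)
    return best_t


def auc_band(auc_value: float) -> str:
    """Qualitative label for an AUC on the Swets scale."""
    if not 0.0 <= auc_value <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if auc_value > 0.9:
        return "excellent"
    if auc_value > 0.8:
        return "good"
    if auc_value > 0.7:
        return "fair"
    if auc_value > 0.6:
        return "poor"
    return "fail"
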