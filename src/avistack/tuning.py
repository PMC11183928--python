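"""Model selection: cross-validated omission filtering and minimum AICc.

Candidate models differ in feature combination (FC; subsets of L, Q, P, T, H)
and regularization multiplier (RM). Each candidate is scored by

* its mean test omission rate over k-fold cross-validation, where the
  threshold is the 10th percentile of training-presence suitability and a
  held-out presence is omitted when it scores strictly below it, and
* the small-sample Akaike information criterion of a final fit to all
  records: AICc = 2K - 2 lnL + 2K(K+1)/(n - K - 1), with K the number of
  non-zero coefficients and lnL the sum over presences of the log normalized
  raw probability.

Candidates with mean omission below the cap (default 0.05) form the feasible
set; among them the minimum-AICc candidate wins (ties: smaller K, smaller RM,
then grid order). If nothing is feasible the lowest-omission candidate is
returned with a warning flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureSet, build_features
from .maxent import MaxentFit, fit_maxent

__all__ = [
    "TuningGrid",
    "ModelScore",
    "TuningResult",
    "crossval_folds",
    "omission_rate",
    "compute_aicc",
    "select_candidate",
    "tune",
]

DEFAULT_FEATURE_COMBINATIONS = ("L", "LQ", "LQH", "LQHP", "LQHPT", "H")
DEFAULT_RMS = tuple(np.arange(0.5, 4.01, 0.5))


@dataclass(frozen=True)
class TuningGrid:
    """Candidate feature combinations and regularization multipliers."""

    feature_combinations: tuple[str, ...] = DEFAULT_FEATURE_COMBINATIONS
    rms: tuple[float, ...] = DEFAULT_RMS

    def __post_init__(self) -> None:
        if not self.feature_combinations or not self.rms:
            raise ValueError("tuning grid must be non-empty")
        for fc in self.feature_combinations:
            bad = set(fc) - set("LQPHT")
            if bad:
                raise ValueError(f"invalid feature combination {fc!r}")

    def candidates(self) -> list[tuple[str, float]]:
        return [(fc, float(rm)) for fc in self.feature_combinations for rm in self.rms]


@dataclass
class ModelScore:
    """Per-candidate cross-validation and information-criterion scores."""

    fc: str
    rm: float
    omission: float
    aicc: float
    k: int
    lnl: float
    n: int
    valid: bool
    selected: bool = False


@dataclass
class TuningResult:
    fc: str
    rm: float
    scores: list[ModelScore]
    feasible: bool               # False => omission cap unmet everywhere, fallback used
    fit: MaxentFit | None = None
    feature_set: FeatureSet | None = None

    def score_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.scores])


def crossval_folds(n_records: int, k: int, seed: int) -> np.ndarray:
    """Random partition of n records into k folds with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_records < k:
        raise ValueError(f"need at least k={k} records, got {n_records}")
    rng = np.random.default_rng(seed)
    assignment = np.arange(n_records) % k
    rng.shuffle(assignment)
    return assignment


def omission_rate(train_scores, test_scores, rule: str = "ten_percentile_training") -> float:
    """Fraction of test presences scoring strictly below the training threshold.

    The threshold is the 10th percentile of the training-presence scores.
    """
    if rule != "ten_percentile_training":
        raise ValueError(f"unknown omission rule {rule!r}")
    train = np.asarray(train_scores, dtype=float)
    test = np.asarray(test_scores, dtype=float)
    if train.size == 0 or test.size == 0:
        raise ValueError("train and test score lists must be non-empty")
    threshold = np.percentile(train, 10.0)
    return float(np.mean(test < threshold))


def compute_aicc(fit: MaxentFit, presence_design: np.ndarray) -> tuple[float, int, float, bool]:
    """AICc of a fit: returns (aicc, K, lnL, valid).

    lnL sums the log normalized raw probability over the presences; K counts
    non-zero coefficients; the candidate is invalid when n - K - 1 <= 0.
    """
    presence_design = np.atleast_2d(np.asarray(presence_design, dtype=float))
    n = presence_design.shape[0]
    if n < 1:
        raise ValueError("at least one presence is required")
    k = fit.n_active
    lnl = float(np.sum(presence_design @ fit.lam - fit.log_z))
    if n - k - 1 <= 0:
        return np.nan, k, lnl, False
    aicc = 2.0 * k - 2.0 * lnl + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    return float(aicc), k, lnl, True


def select_candidate(scores: list[ModelScore], omission_cap: float = 0.05
                     ) -> tuple[ModelScore, bool]:
    """Filter-then-argmin selection over a candidate score table.

    Candidates with mean test omission below the cap form the feasible set;
    among them the minimum-AICc candidate wins, ties broken by smaller K,
    then smaller RM, then table order. With an empty feasible set the
    lowest-omission valid candidate is returned with ``feasible=False``.
    """
    if not any(s.valid for s in scores):
        raise ValueError(
            "AICc undefined for every candidate (K >= n - 1 throughout): "
            "use more records or sparser feature combinations"
        )
    feasible = [s for s in scores if s.valid and s.omission < omission_cap]
    if feasible:
        return min(feasible, key=lambda s: (s.aicc, s.k, s.rm)), True
    valid_scores = [s for s in scores if s.valid]
    return min(valid_scores, key=lambda s: (s.omission, s.aicc)), False


def tune(
    presence_values: dict[str, np.ndarray],
    background_values: dict[str, np.ndarray],
    grid: TuningGrid | None = None,
    k: int = 10,
    omission_cap: float = 0.05,
    seed: int = 0,
    categorical_legend: dict[str, list[int]] | None = None,
    n_knots: int = 10,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> TuningResult:
    """Select (FC, RM) for one species by omission filtering and minimum AICc."""
    grid = grid or TuningGrid()
    n = len(next(iter(presence_values.values())))
    folds = crossval_folds(n, k, seed)
    scores: list[ModelScore] = []
    designs: dict[str, tuple[FeatureSet, np.ndarray, np.ndarray]] = {}

    for fc in grid.feature_combinations:
        fs = build_features(background_values, classes=fc, n_knots=n_knots,
                            categorical_legend=categorical_legend)
        b_design, _ = fs.design_matrix(background_values)
        p_design, _ = fs.design_matrix(presence_values)
        designs[fc] = (fs, b_design, p_design)

    for fc, rm in grid.candidates():
        fs, b_design, p_design = designs[fc]
        omissions = []
        for fold in range(k):
            train = p_design[folds != fold]
            test = p_design[folds == fold]
            fit = fit_maxent(train, b_design, fs, rm=rm, max_iter=max_iter, tol=tol,
                             feature_label=fc)
            train_scores = train @ fit.lam
            test_scores = test @ fit.lam
            omissions.append(omission_rate(train_scores, test_scores))
        full_fit = fit_maxent(p_design, b_design, fs, rm=rm, max_iter=max_iter, tol=tol,
                              feature_label=fc)
        aicc, kk, lnl, valid = compute_aicc(full_fit, p_design)
        scores.append(ModelScore(fc=fc, rm=rm, omission=float(np.mean(omissions)),
                                 aicc=aicc, k=kk, lnl=lnl, n=n, valid=valid))

    chosen, ok = select_candidate(scores, omission_cap)
    chosen.selected = True

    fs, b_design, p_design = designs[chosen.fc]
    final_fit = fit_maxent(p_design, b_design, fs, rm=chosen.rm, max_iter=max_iter,
                           tol=tol, feature_label=chosen.fc)
    return TuningResult(fc=chosen.fc, rm=chosen.rm, scores=scores, feasible=ok,
                        fit=final_fit, feature_set=fs)
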