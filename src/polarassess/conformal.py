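"""Split-conformal uncertainty for polarization scores.

Nonconformity is |score - label|.  Quantiles are calibrated by stratified
5-fold cross-calibration, and each (score, q-hat) pair maps to exactly one
of four classes: polarized, unpolarized, intermediate, uncertain.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .polarization_models import LabeledFeatureSet, polarization_score, train_state_model

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_FOLDS",
    "CLASS_LABELS",
    "ConformalCalibration",
    "nonconformity",
    "cross_calibrate",
    "conformal_quantile",
    "classify",
    "classify_array",
]

DEFAULT_ALPHA = 0.05
DEFAULT_FOLDS = 5

CLASS_LABELS = ("polarized", "unpolarized", "intermediate", "uncertain")


def nonconformity(score, label):
    """|score - label| for label in {0, 1}; accepts scalars or arrays."""
    return np.abs(np.asarray(score, dtype=float) - np.asarray(label, dtype=float))


@dataclass
class ConformalCalibration:
    """Calibration nonconformity scores for one state, with quantile lookup."""

    state_id: str
    scores: np.ndarray  # one nonconformity score per calibration cell
    folds: int = DEFAULT_FOLDS
    seed: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.shape[0] < 1:
            raise ValueError("calibration scores must be a non-empty 1-d array")
        if ((self.scores < -1e-12) | (self.scores > 1 + 1e-12)).any():
            raise ValueError("nonconformity scores must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def q_hat(self, alpha: float = DEFAULT_ALPHA) -> float:
        return conformal_quantile(self.scores, alpha)


def conformal_quantile(s_nc: Iterable[float], alpha: float) -> float:
    """Finite-sample conformal quantile of calibration nonconformity scores.

    Returns the k-th smallest score with k = ceil((N+1)(1-alpha)), capped
    at N, i.e. the empirical quantile at level ceil((N+1)(1-alpha))/N.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    s = np.sort(np.asarray(list(s_nc), dtype=float))
    n = s.shape[0]
    if n < 1:
        raise ValueError("need at least one calibration score")
    # tiny slack guards against float rounding of (N+1)(1-alpha) at integers
    k = math.ceil((n + 1) * (1 - alpha) - 1e-9)
    k = min(max(k, 1), n)
    return float(s[k - 1])


def cross_calibrate(
    data: LabeledFeatureSet,
    kind: str = "svm_linear",
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    state_id: str = "",
) -> ConformalCalibration:
    """K-fold cross-calibration: each cell's nonconformity comes from the
    model trained without its fold; every cell contributes exactly one score.

    Folds are stratified by label when the smaller class allows it (plain
    K-fold otherwise, e.g. leave-one-out); any training fold missing a class
    is an error.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > data.n_cells:
        raise ValueError(f"cannot split {data.n_cells} cells into {folds} folds")
    y = data.labels
    min_class = min(data.n_polarized, data.n_unpolarized)
    if min_class == 0:
        raise ValueError("calibration data must contain both classes")
    if folds <= min_class:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    s_nc = np.full(data.n_cells, np.nan)
    for train_idx, cal_idx in splitter.split(data.features, y):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a training fold is missing one of the classes")
        model = train_state_model(data.subset(train_idx), kind=kind, seed=seed)
        scores = polarization_score(model, data.features[cal_idx])
        s_nc[cal_idx] = nonconformity(scores, y[cal_idx])
    assert not np.isnan(s_nc).any()
    return ConformalCalibration(state_id=state_id, scores=s_nc, folds=folds, seed=seed)


def classify(score: float, q_hat: float) -> str:
    """Four-way class from a polarization score and conformal quantile.

    polarized:    score > 1 - q_hat and score >= q_hat
    unpolarized:  score <= 1 - q_hat and score < q_hat
    intermediate: score > 1 - q_hat and score < q_hat   (both classes fit)
    uncertain:    score <= 1 - q_hat and score >= q_hat (neither class fits)
    """
    above = score > 1 - q_hat
    ge = score >= q_hat
    if above and ge:
        return "polarized"
    if not above and not ge:
        return "unpolarized"
    if above:
        return "intermediate"
    return "uncertain"


def classify_array(scores: np.ndarray, q_hat: float) -> np.ndarray:
    """Vectorized :func:`classify`."""
    scores = np.asarray(scores, dtype=float)
    above = scores > 1 - q_hat
    ge = scores >= q_hat
    out = np.empty(scores.shape, dtype=object)
    out[above & ge] = "polarized"
    out[~above & ~ge] = "unpolarized"
    out[above & ~ge] = "intermediate"
    out[~above & ge] = "uncertain"
    return out.astype(str)
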