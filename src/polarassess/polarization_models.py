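"""Per-state classifiers producing polarization scores in [0, 1].

The default scorer is a linear SVM whose decision values are mapped to
probabilities by Platt (sigmoid) scaling fit on cross-validated decision
values.  Logistic-regression and random-forest trainers are provided for
the benchmarking harness; a one-round self-training variant exists but is
off by default for prediction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict, train_test_split
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_KINDS",
    "DEFAULT_SVM_C",
    "LabeledFeatureSet",
    "TrainedStateModel",
    "HoldoutResult",
    "train_state_model",
    "train_semi_supervised",
    "polarization_score",
    "auroc",
    "evaluate_repeated_holdout",
]

CLASSIFIER_KINDS = ("svm_linear", "logistic", "random_forest")

#: regularization constant for the linear SVM (the classic default)
DEFAULT_SVM_C = 1.0

_LINEAR_KINDS = ("svm_linear", "logistic")


@dataclass
class LabeledFeatureSet:
    """Feature matrix with binary labels: 0 = unpolarized, 1 = fully polarized."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-d")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must align 1:1 with feature rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    @property
    def n_cells(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_polarized(self) -> int:
        return int(self.labels.sum())

    @property
    def n_unpolarized(self) -> int:
        return int((self.labels == 0).sum())

    def subset(self, idx: np.ndarray) -> "LabeledFeatureSet":
        return LabeledFeatureSet(self.features[idx], self.labels[idx])


@dataclass
class TrainedStateModel:
    """Fitted classifier for one polarization state.

    Linear kinds are stored as explicit weights plus sigmoid calibration
    parameters, so scoring is pure arithmetic and the model round-trips
    through plain arrays.  Random forests keep the fitted estimator.
    """

    state_id: str
    kind: str
    weights: Optional[np.ndarray] = None
    intercept: float = 0.0
    calib_a: float = 1.0
    calib_b: float = 0.0
    estimator: Optional[object] = None
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind in _LINEAR_KINDS and self.weights is None:
            raise ValueError(f"{self.kind} model requires linear weights")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n_features(self) -> int:
        if self.weights is not None:
            return self.weights.shape[0]
        return int(self.estimator.n_features_in_)  # type: ignore[union-attr]

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        features = _check_width(features, self.n_features)
        if self.kind in _LINEAR_KINDS:
            return features @ self.weights + self.intercept
        return self.estimator.predict_proba(features)[:, 1]  # type: ignore[union-attr]

    def predict_score(self, features: np.ndarray) -> np.ndarray:
        f = self.decision_values(features)
        if self.kind in _LINEAR_KINDS:
            s = expit(self.calib_a * f + self.calib_b)
        else:
            s = f
        return np.clip(s, 0.0, 1.0)


@dataclass
class HoldoutResult:
    """Per-repeat holdout AUROCs with mean/median summaries."""

    aurocs: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.aurocs))

    @property
    def median(self) -> float:
        return float(np.median(self.aurocs))


def _check_width(features: np.ndarray, expected: int) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[None, :]
    if features.shape[1] != expected:
        raise ValueError(
            f"feature width {features.shape[1]} does not match model width {expected}"
        )
    return features


def _check_trainable(data: LabeledFeatureSet) -> None:
    if data.n_polarized == 0 or data.n_unpolarized == 0:
        raise ValueError("training data must contain both classes")
    if min(data.n_polarized, data.n_unpolarized) < 2:
        raise ValueError("need at least 2 cells per class to train")
    if data.n_cells < 10:
        warnings.warn(
            f"only {data.n_cells} training cells; expect a poor fit", stacklevel=3
        )


def _fit_platt(
    dec: np.ndarray, labels: np.ndarray, max_iter: int = 1000
) -> tuple[float, float]:
    """Sigmoid P(polarized) = expit(a*f + b) fit to decision values."""
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=max_iter)
    lr.fit(dec[:, None], labels)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def train_state_model(
    data: LabeledFeatureSet,
    kind: str = "svm_linear",
    seed: int = 0,
    state_id: str = "",
    C: float = DEFAULT_SVM_C,
) -> TrainedStateModel:
    """Fit a classifier for one state; score = calibrated P(fully polarized)."""
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    _check_trainable(data)
    X, y = data.features, data.labels
    meta = {
        "n_polarized": data.n_polarized,
        "n_unpolarized": data.n_unpolarized,
        "seed": int(seed),
        "n_features": data.n_features,
    }
    if kind == "svm_linear":
        svc = SVC(kernel="linear", C=C)
        svc.fit(X, y)
        w = svc.coef_[0].copy()
        b = float(svc.intercept_[0])
        n_splits = min(5, data.n_polarized, data.n_unpolarized)
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        dec = cross_val_predict(
            SVC(kernel="linear", C=C), X, y, cv=cv, method="decision_function"
        )
        a, b0 = _fit_platt(dec, y)
        return TrainedStateModel(
            state_id=state_id, kind=kind, weights=w, intercept=b,
            calib_a=a, calib_b=b0, training_meta=meta,
        )
    if kind == "logistic":
        lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
        lr.fit(X, y)
        return TrainedStateModel(
            state_id=state_id, kind=kind,
            weights=lr.coef_[0].copy(), intercept=float(lr.intercept_[0]),
            calib_a=1.0, calib_b=0.0, training_meta=meta,
        )
    rf = RandomForestClassifier(n_estimators=100, random_state=seed)
    rf.fit(X, y)
    return TrainedStateModel(
        state_id=state_id, kind=kind, estimator=rf, training_meta=meta
    )


def polarization_score(model: TrainedStateModel, features: np.ndarray) -> np.ndarray:
    """Scores in [0, 1], monotone non-decreasing in the model's decision value."""
    return model.predict_score(features)


def train_semi_supervised(
    labeled: LabeledFeatureSet,
    unlabeled: np.ndarray,
    base_kind: str = "svm_linear",
    seed: int = 0,
    state_id: str = "",
    threshold: float = 0.5,
) -> TrainedStateModel:
    """One self-training round: fit, hard-label the unlabeled pool, refit.

    Experimental; not used for prediction by default.
    """
    base = train_state_model(labeled, kind=base_kind, seed=seed, state_id=state_id)
    unlabeled = np.asarray(unlabeled, dtype=float)
    if unlabeled.size == 0:
        return base
    pseudo = (polarization_score(base, unlabeled) >= threshold).astype(int)
    combined = LabeledFeatureSet(
        np.vstack([labeled.features, unlabeled]),
        np.concatenate([labeled.labels, pseudo]),
    )
    model = train_state_model(combined, kind=base_kind, seed=seed, state_id=state_id)
    model.training_meta["semi_supervised"] = True
    model.training_meta["n_pseudo_labeled"] = int(unlabeled.shape[0])
    return model


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney normalization, ties count 1/2)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def evaluate_repeated_holdout(
    data: LabeledFeatureSet,
    repeats: int = 20,
    train_frac: float = 0.7,
    kind: str = "svm_linear",
    seed: int = 0,
) -> HoldoutResult:
    """Repeated stratified holdout: train on *train_frac*, AUROC on the rest."""
    _check_trainable(data)
    if min(data.n_polarized, data.n_unpolarized) < 4:
        raise ValueError("each class needs at least 4 cells for a stratified 70/30 split")
    rng = np.random.default_rng(seed)
    aurocs: list[float] = []
    for _ in range(repeats):
        split_seed = int(rng.integers(0, 2**31 - 1))
        idx_train, idx_test = train_test_split(
            np.arange(data.n_cells),
            train_size=train_frac,
            stratify=data.labels,
            random_state=split_seed,
        )
        model = train_state_model(data.subset(idx_train), kind=kind, seed=split_seed)
        scores = polarization_score(model, data.features[idx_test])
        aurocs.append(auroc(scores, data.labels[idx_test]))
    return HoldoutResult(aurocs=aurocs)
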