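"""Training, evaluation and per-class probability reporting.

Five classifier families are compared on the scaled, feature-selected
table: decision tree (DT), random forest (RF), k-nearest neighbours (KNN),
RBF-kernel support vector machine (SVM) and a single-hidden-layer
multi-layer perceptron (MLP). Evaluation uses a seed-controlled stratified
70/30 split and stratified 10-fold cross-validation, scored with
macro-averaged metrics over the six execution classes:

    accuracy    = mean_k (TP_k + TN_k) / N
    specificity = mean_k TN_k / (TN_k + FP_k)
    sensitivity = mean_k TP_k / (TP_k + FN_k)
    precision   = mean_k TP_k / (TP_k + FP_k)

where the confusion matrix holds actual classes along rows and predicted
classes along columns, and TP/TN/FP/FN are the one-vs-rest counts of class
k. Classes with a zero denominator are excluded from that metric's mean
(with a warning) rather than contributing a non-finite term.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ContractError, DataError, ParameterError
from .features import FeatureTable, ScalerParams, SelectedFeatureSet, apply_scaler
from .imu_model import LABEL_NAMES, SquatLabel

logger = logging.getLogger(__name__)

ALGORITHMS = ("DT", "RF", "KNN", "SVM", "MLP")
N_CLASSES = len(SquatLabel)
DEFAULT_MIXED_ERROR_THRESHOLD = 0.25


def make_estimator(algo: str, seed: int = 0, **hyperparams):
    """Construct a classifier with the package's default hyperparameters."""
    if algo == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=seed, **hyperparams)
    if algo == "RF":
        hp = {"n_estimators": 100, **hyperparams}
        return RandomForestClassifier(random_state=seed, **hp)
    if algo == "KNN":
        hp = {"n_neighbors": 5, "metric": "euclidean", **hyperparams}
        return KNeighborsClassifier(**hp)
    if algo == "SVM":
        hp = {"kernel": "rbf", "C": 1.0, "probability": True,
              "decision_function_shape": "ovr", **hyperparams}
        return SVC(random_state=seed, **hp)
    if algo == "MLP":
        hp = {"hidden_layer_sizes": (100,), "activation": "relu",
              "max_iter": 500, **hyperparams}
        return MLPClassifier(random_state=seed, **hp)
    raise ParameterError(f"unknown algorithm {algo!r}; expected one of {ALGORITHMS}")


@dataclass
class ConfusionMatrix:
    """6×6 counts, rows = actual class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ParameterError(f"expected a {N_CLASSES}×{N_CLASSES} matrix")
        if (self.counts < 0).any():
            raise ParameterError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(LABEL_NAMES), columns=list(LABEL_NAMES))

    def to_csv(self, path: str | Path) -> Path:
        self.to_frame().to_csv(path)
        return Path(path)


@dataclass
class MacroMetrics:
    accuracy: float
    specificity: float
    sensitivity: float
    precision: float
    per_class: pd.DataFrame | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy, "specificity": self.specificity,
            "sensitivity": self.sensitivity, "precision": self.precision,
        }


def confusion(truths: Sequence[int], preds: Sequence[int]) -> ConfusionMatrix:
    truths = np.asarray(truths, dtype=int)
    preds = np.asarray(preds, dtype=int)
    if truths.shape != preds.shape:
        raise DataError("truths and preds must have equal length")
    if truths.size and (
        truths.min() < 0 or truths.max() >= N_CLASSES
        or preds.min() < 0 or preds.max() >= N_CLASSES
    ):
        raise DataError("label values outside the six squat classes")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (truths, preds), 1)
    return ConfusionMatrix(cm)


def macro_metrics(cm: ConfusionMatrix) -> MacroMetrics:
    """Macro-averaged one-vs-rest metrics from a confusion matrix."""
    C = cm.counts
    N = cm.n
    if N == 0:
        raise ParameterError("empty confusion matrix")
    tp = np.diag(C).astype(float)
    fn = C.sum(axis=1) - tp
    fp = C.sum(axis=0) - tp
    tn = N - tp - fn - fp

    def macro(num: np.ndarray, den: np.ndarray, name: str) -> float:
        ok = den > 0
        if not ok.all():
            excluded = [LABEL_NAMES[i] for i in np.flatnonzero(~ok)]
            logger.warning("%s: zero denominator for %s, excluded from mean", name, excluded)
        if not ok.any():
            return 0.0
        return float(np.mean(num[ok] / den[ok]))

    per_class = pd.DataFrame(
        {"TP": tp, "TN": tn, "FP": fp, "FN": fn}, index=list(LABEL_NAMES)
    )
    return MacroMetrics(
        accuracy=macro(tp + tn, np.full(N_CLASSES, float(N)), "accuracy"),
        specificity=macro(tn, tn + fp, "specificity"),
        sensitivity=macro(tp, tp + fn, "sensitivity"),
        precision=macro(tp, tp + fp, "precision"),
        per_class=per_class,
    )


@dataclass
class TrainedModel:
    """A fitted classifier bundled with everything prediction needs."""

    algo: str
    estimator: object
    scaler: ScalerParams | None
    feature_set: SelectedFeatureSet | None
    class_order: list[int]
    seed: int
    holdout: MacroMetrics | None = None
    holdout_cm: ConfusionMatrix | None = None
    mixed_error_threshold: float = DEFAULT_MIXED_ERROR_THRESHOLD
    meta: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        if self.feature_set is not None:
            return list(self.feature_set.names)
        return list(self.scaler.feature_names) if self.scaler else []

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "algo": self.algo, "seed": self.seed,
                    "n_features": len(self.feature_names),
                    "class_order": [SquatLabel(c).name for c in self.class_order],
                    "holdout": self.holdout.as_dict() if self.holdout else None,
                },
                fh, indent=2,
            )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _select_columns(table: FeatureTable, feature_set: SelectedFeatureSet | None) -> np.ndarray:
    if feature_set is None:
        return table.values.to_numpy(float)
    missing = [n for n in feature_set.names if n not in table.values.columns]
    if missing:
        raise ContractError(f"table is missing selected features: {missing[:5]}")
    return table.values[feature_set.names].to_numpy(float)


def train(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    algo: str = "MLP",
    seed: int = 0,
    hyperparams: dict | None = None,
    scaler: ScalerParams | None = None,
    feature_set: SelectedFeatureSet | None = None,
    test_size: float = 0.3,
) -> TrainedModel:
    """Fit one classifier on a seed-controlled stratified 70/30 split.

    The held-out 30% is scored with the macro metrics and kept on the model
    for reporting; `scaler`/`feature_set` document how the table was
    prepared and travel with the bundle.
    """
    y = table.labels if labels is None else np.asarray(labels, dtype=int)
    if y is None:
        raise ParameterError("labels are required for training")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise DataError(
            f"every class needs ≥ 2 rows for a stratified split; got {dict(zip(classes, counts))}"
        )
    X = _select_columns(table, feature_set)
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    est = make_estimator(algo, seed=seed, **(hyperparams or {}))
    est.fit(Xtr, ytr)
    preds = est.predict(Xte)
    cm = confusion(yte, preds)
    return TrainedModel(
        algo=algo, estimator=est, scaler=scaler, feature_set=feature_set,
        class_order=[int(c) for c in est.classes_], seed=seed,
        holdout=macro_metrics(cm), holdout_cm=cm,
    )


def cross_validate(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    algo: str = "MLP",
    k: int = 10,
    seed: int = 0,
    hyperparams: dict | None = None,
    feature_set: SelectedFeatureSet | None = None,
) -> tuple[list[MacroMetrics], MacroMetrics]:
    """Stratified k-fold CV: per-fold macro metrics plus their mean."""
    y = table.labels if labels is None else np.asarray(labels, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ParameterError(
            f"smallest class has {counts.min()} rows < k={k}; use a smaller k"
        )
    X = _select_columns(table, feature_set)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[MacroMetrics] = []
    for tr, te in skf.split(X, y):
        est = make_estimator(algo, seed=seed, **(hyperparams or {}))
        est.fit(X[tr], y[tr])
        folds.append(macro_metrics(confusion(y[te], est.predict(X[te]))))
    mean = MacroMetrics(
        accuracy=float(np.mean([f.accuracy for f in folds])),
        specificity=float(np.mean([f.specificity for f in folds])),
        sensitivity=float(np.mean([f.sensitivity for f in folds])),
        precision=float(np.mean([f.precision for f in folds])),
    )
    return folds, mean


def predict_report(
    model: TrainedModel, row: np.ndarray | pd.Series | FeatureTable
) -> tuple[SquatLabel, np.ndarray, list[str]]:
    """Classify one repetition: label, 6-class probability vector, advice codes.

    Probabilities come from the model family's native estimates (softmax for
    the MLP); advice codes list every *error* class whose probability
    reaches the mixed-error threshold, enabling combined feedback.
    """
    names = model.feature_names
    if not names:
        # bare model (no scaler/selection bundled): validate by width only
        n_expected = int(getattr(model.estimator, "n_features_in_", 0))
        if isinstance(row, FeatureTable):
            X = row.values.to_numpy(float)
        elif isinstance(row, pd.Series):
            X = row.to_numpy(float)[None, :]
        else:
            X = np.atleast_2d(np.asarray(row, dtype=float))
        if n_expected and X.shape[1] != n_expected:
            raise ContractError(
                f"feature row has {X.shape[1]} values, model expects {n_expected}"
            )
        return _finish_report(model, X)
    if isinstance(row, FeatureTable):
        missing = [n for n in names if n not in row.values.columns]
        if missing:
            raise ContractError(f"missing features: {missing[:5]}")
        X = row.values[names].to_numpy(float)
    elif isinstance(row, pd.Series):
        missing = [n for n in names if n not in row.index]
        if missing:
            raise ContractError(f"missing features: {missing[:5]}")
        X = row[names].to_numpy(float)[None, :]
    else:
        X = np.atleast_2d(np.asarray(row, dtype=float))
        if X.shape[1] != len(names):
            raise ContractError(
                f"feature row has {X.shape[1]} values, model expects {len(names)}"
            )
    return _finish_report(model, X)


def _finish_report(
    model: TrainedModel, X: np.ndarray
) -> tuple[SquatLabel, np.ndarray, list[str]]:
    raw = model.estimator.predict_proba(X)[0]
    probs = np.zeros(N_CLASSES)
    for p, c in zip(raw, model.class_order):
        probs[c] = p
    probs = probs / probs.sum()
    label = SquatLabel(int(np.argmax(probs)))
    advice = [
        SquatLabel(c).name
        for c in range(N_CLASSES)
        if c != SquatLabel.CO and probs[c] >= model.mixed_error_threshold
    ]
    return label, probs, advice


def evaluate_all(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    seed: int = 0,
    algos: Sequence[str] = ALGORITHMS,
) -> pd.DataFrame:
    """Train/evaluate every algorithm on the same 70/30 split; metric table."""
    rows = []
    for algo in algos:
        model = train(table, labels, algo=algo, seed=seed)
        rows.append({"classifier": algo, **{k: v for k, v in model.holdout.as_dict().items()}})
    return pd.DataFrame(rows).set_index("classifier")
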