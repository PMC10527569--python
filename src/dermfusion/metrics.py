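"""Multiclass evaluation harness: confusion matrix, metric panel and a
cross-validated classifier roster.

The metric panel covers accuracy, macro sensitivity (recall), macro
precision, macro F1, false-negative rate (1 - macro sensitivity), macro
one-vs-rest AUC, the Fowlkes-Mallows index (geometric mean of macro
precision and macro sensitivity), the multiclass Matthews correlation
coefficient and Cohen's kappa.  Macro averaging is used for the headline
values because one rate per classifier is reported regardless of the class
count; micro-averaged variants are included for transparency.

Classifier names follow MATLAB Classification Learner presets; the mapping
to scikit-learn estimators is documented in :data:`CLASSIFIER_ROSTER` and
each entry can be overridden.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "CLASSIFIER_ROSTER",
    "make_classifier",
    "confusion",
    "compute_metrics",
    "crossval_classify",
]


@dataclass
class ConfusionMatrix:
    """C x C count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_names: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square and match class_names")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    """One row of a classifier-comparison table."""

    accuracy: float
    sensitivity: float
    precision: float
    f1: float
    fnr: float
    fowlkes_mallows: float
    mcc: float
    kappa: float
    auc: float | None = None
    micro_precision: float = 0.0
    micro_sensitivity: float = 0.0
    per_class: dict = field(default_factory=dict)
    elapsed_time: float = 0.0

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "fnr": self.fnr,
            "fowlkes_mallows": self.fowlkes_mallows,
            "mcc": self.mcc,
            "kappa": self.kappa,
            "auc": self.auc,
            "micro_precision": self.micro_precision,
            "micro_sensitivity": self.micro_sensitivity,
            "elapsed_time": self.elapsed_time,
        }
        return out


def confusion(true_labels, predicted_labels, class_names=None) -> ConfusionMatrix:
    """Count matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted labels must have equal length")
    if class_names is None:
        class_names = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label {t!r}/{p!r} not in class_names")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(
    cm: ConfusionMatrix, auc: float | None = None, elapsed_time: float = 0.0
) -> EvalReport:
    """Derive the full metric panel from a confusion matrix.

    Classes absent from both truth and prediction are excluded from the
    macro averages with a warning.  AUC cannot be derived from counts alone
    and is passed through from a probability-capable evaluation (or left
    None).
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    present = (row + col) > 0
    if not present.all():
        warnings.warn("classes absent from both truth and prediction excluded "
                      "from macro averages")
    diag = np.diag(counts)

    recalls = np.array([_safe_div(diag[i], row[i]) for i in range(len(row))])
    precisions = np.array([_safe_div(diag[i], col[i]) for i in range(len(col))])
    f1s = np.array([
        _safe_div(2 * precisions[i] * recalls[i], precisions[i] + recalls[i])
        for i in range(len(row))
    ])

    sensitivity = float(recalls[present].mean())
    precision = float(precisions[present].mean())
    f1 = float(f1s[present].mean())
    accuracy = float(diag.sum() / total)

    # Multiclass MCC from the confusion matrix
    c = diag.sum()
    s = total
    num = c * s - float(col @ row)
    den = np.sqrt((s * s - float(col @ col)) * (s * s - float(row @ row)))
    mcc = 0.0 if den == 0 else float(num / den)

    po = accuracy
    pe = float(col @ row) / (s * s)
    kappa = 1.0 if (1.0 - pe) == 0 and po == 1.0 else _safe_div(po - pe, 1.0 - pe)

    per_class = {
        str(cm.class_names[i]): {
            "recall": float(recalls[i]),
            "precision": float(precisions[i]),
            "f1": float(f1s[i]),
            "support": int(row[i]),
        }
        for i in range(len(row))
        if present[i]
    }
    return EvalReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        precision=precision,
        f1=f1,
        fnr=1.0 - sensitivity,
        fowlkes_mallows=float(np.sqrt(precision * sensitivity)),
        mcc=mcc,
        kappa=float(kappa),
        auc=auc,
        micro_precision=accuracy,
        micro_sensitivity=accuracy,
        per_class=per_class,
        elapsed_time=elapsed_time,
    )


def _narrow_nn():
    return MLPClassifier(hidden_layer_sizes=(10,), max_iter=400, random_state=0)


def _medium_nn():
    return MLPClassifier(hidden_layer_sizes=(25,), max_iter=400, random_state=0)


def _bilayered_nn():
    return MLPClassifier(hidden_layer_sizes=(10, 10), max_iter=400, random_state=0)


#: MATLAB Classification Learner preset -> scikit-learn configuration.
CLASSIFIER_ROSTER = {
    "fine_tree": lambda: DecisionTreeClassifier(max_leaf_nodes=100, random_state=0),
    "fine_knn": lambda: KNeighborsClassifier(n_neighbors=1),
    "medium_knn": lambda: KNeighborsClassifier(n_neighbors=10),
    "weighted_knn": lambda: KNeighborsClassifier(n_neighbors=10, weights="distance"),
    "quadratic_svm": lambda: SVC(kernel="poly", degree=2, C=1.0, gamma="scale"),
    "bagged_tree": lambda: RandomForestClassifier(n_estimators=30, random_state=0),
    "narrow_nn": _narrow_nn,
    "medium_nn": _medium_nn,
    "bilayered_nn": _bilayered_nn,
}


def make_classifier(name: str, **overrides):
    if name not in CLASSIFIER_ROSTER:
        raise ValueError(
            f"unknown classifier {name!r}; choose from {sorted(CLASSIFIER_ROSTER)}"
        )
    clf = CLASSIFIER_ROSTER[name]()
    if overrides:
        clf.set_params(**overrides)
    return clf


def _fold_scores(clf, test_x, n_classes: int) -> np.ndarray:
    """Class scores for AUC: probabilities, or min-max scaled decision values."""
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(test_x)
    dec = clf.decision_function(test_x)
    if dec.ndim == 1:
        dec = np.column_stack([-dec, dec])
    lo, hi = dec.min(), dec.max()
    scaled = (dec - lo) / (hi - lo) if hi > lo else np.full_like(dec, 0.5)
    rowsum = scaled.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return scaled / rowsum


def crossval_classify(
    data: FeatureMatrix,
    classifier_name: str = "fine_knn",
    folds: int = 10,
    seed: int = 0,
    classifier_overrides: dict | None = None,
) -> EvalReport:
    """Stratified cross-validated evaluation with pooled out-of-fold predictions.

    Every sample is predicted exactly once (by the model that never saw it),
    the pooled predictions form one confusion matrix, and the metric panel
    is computed from it.  AUC is macro one-vs-rest on the pooled class
    scores.  Deterministic given (data, classifier, folds, seed).
    """
    classes, counts = np.unique(data.labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("evaluation needs at least 2 classes")
    n_folds = max(2, min(folds, int(counts.min())))
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)

    x, y = data.values, data.labels
    pred = np.empty_like(y)
    scores = np.zeros((len(y), classes.size))
    t_start = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on tiny folds
        for train_idx, test_idx in splitter.split(x, y):
            clf = make_classifier(classifier_name, **(classifier_overrides or {}))
            clf.fit(x[train_idx], y[train_idx])
            pred[test_idx] = clf.predict(x[test_idx])
            fold_scores = _fold_scores(clf, x[test_idx], classes.size)
            col_of = {c: k for k, c in enumerate(clf.classes_)}
            for k, c in enumerate(classes):
                if c in col_of:
                    scores[test_idx, k] = fold_scores[:, col_of[c]]
    elapsed = time.perf_counter() - t_start

    try:
        if classes.size == 2:
            auc = float(roc_auc_score(y, scores[:, 1]))
        else:
            auc = float(
                roc_auc_score(y, scores, multi_class="ovr", average="macro",
                              labels=classes)
            )
    except ValueError:
        auc = None
    cm = confusion(y, pred, class_names=classes.tolist())
    return compute_metrics(cm, auc=auc, elapsed_time=elapsed)
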