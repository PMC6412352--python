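"""Binary maximum-margin classification and its evaluation.

The selected feature columns feed a soft-margin kernel SVM (RBF kernel,
C=1, bandwidth 1/(n_features * var(X)) by default — all config-exposed).
Evaluation reports the confusion matrix with drowsy as the positive
class, accuracy as 100*(TP+TN)/(TP+FP+TN+FN), the ROC curve swept over
the decision score, and the trapezoid AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.svm import SVC

__all__ = [
    "SVMConfig",
    "ConfusionMatrix",
    "EvalReport",
    "train_classifier",
    "evaluate",
    "accuracy_from_counts",
]


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"  # "scale" == 1 / (n_features * var(X))


@dataclass
class ConfusionMatrix:
    """Counts with drowsy = positive: TP drowsy->drowsy, TN awake->awake."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return accuracy_from_counts(self.tp, self.tn, self.fp, self.fn)


def accuracy_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Accuracy percentage 100*(TP+TN)/(TP+FP+TN+FN)."""
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (tp + tn) / total


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    accuracy: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "confusion": {
                "tp": self.confusion.tp,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
            },
            "accuracy": self.accuracy,
            "auc": self.auc,
            "roc": [
                {"fpr": float(f), "tpr": float(t)}
                for f, t in zip(self.roc_fpr, self.roc_tpr)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def train_classifier(
    X_selected: np.ndarray, y: np.ndarray, cfg: SVMConfig | None = None
) -> SVC:
    """Fit the soft-margin kernel classifier on the selected columns.

    Exposes binary prediction (``predict``) and a real-valued decision
    score (``decision_function``) for ROC sweeping.  Single-class input is
    an error: a margin between classes needs both.
    """
    cfg = cfg or SVMConfig()
    y = np.asarray(y, int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("training needs at least 2 samples of each class")
    clf = SVC(kernel=cfg.kernel, C=cfg.C, gamma=cfg.gamma)
    clf.fit(np.asarray(X_selected, float), y)
    return clf


def evaluate(clf: SVC, X_test_selected: np.ndarray, y_test: np.ndarray) -> EvalReport:
    """Confusion counts, accuracy, ROC over the decision score, trapezoid AUC."""
    X = np.asarray(X_test_selected, float)
    y = np.asarray(y_test, int)
    if len(y) == 0:
        raise ValueError("test set is empty")
    pred = clf.predict(X)
    cm = ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )
    scores = clf.decision_function(X)
    if len(np.unique(y)) == 2:
        fpr, tpr, _ = _roc_curve(y, scores, pos_label=1)
        auc = float(_trapezoid_auc(fpr, tpr))
    else:  # degenerate single-class test set: ROC undefined
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
        auc = float("nan")
    return EvalReport(
        confusion=cm, accuracy=cm.accuracy, roc_fpr=fpr, roc_tpr=tpr, auc=auc
    )
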