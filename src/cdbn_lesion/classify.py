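"""Gradient-boosted-tree classification head and evaluation metrics.

The 256-dimensional CDBN features feed a boosted ensemble of 100 decision
trees (XGBoost, second-order boosting); everything beyond the tree count
uses the library defaults, frozen here for reproducibility. Evaluation
reports a 3x3 confusion matrix in fixed class order plus accuracy and
macro-averaged precision/recall/F1 (per-class F1 = 2PR/(P+R), averaged
unweighted; a class with no true and no predicted positives contributes 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

from .synth import CLASSES

__all__ = [
    "LabeledFeatures",
    "EvalReport",
    "train_classifier",
    "predict",
    "evaluate",
    "report_from_confusion",
    "stratified_split",
]


@dataclass
class LabeledFeatures:
    """Feature matrix with class labels and a split tag."""

    features: np.ndarray           # (N, d) float
    labels: list[str]
    split: str = ""                # "train" / "test" / ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError(f"features must be 2-D, got shape {self.features.shape}")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("one label per feature row required")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"labels outside the class set: {bad}")

    def encoded_labels(self) -> np.ndarray:
        index = {c: i for i, c in enumerate(CLASSES)}
        return np.asarray([index[l] for l in self.labels], dtype=np.int64)


@dataclass
class EvalReport:
    """Confusion matrix (rows = true, columns = predicted) and summary metrics."""

    confusion: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    misclassified: int
    per_class_f1: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_order": list(CLASSES),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "misclassified": self.misclassified,
            "per_class_f1": self.per_class_f1,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        lines = ["confusion matrix (rows=true, cols=predicted):"]
        width = max(len(c) for c in CLASSES)
        header = " " * (width + 2) + "  ".join(f"{c[:6]:>6}" for c in CLASSES)
        lines.append(header)
        for i, c in enumerate(CLASSES):
            row = "  ".join(f"{int(n):>6}" for n in self.confusion[i])
            lines.append(f"{c:<{width}}  {row}")
        lines.append(
            f"accuracy={self.accuracy:.4f}  macro_f1={self.macro_f1:.4f}  "
            f"macro_precision={self.macro_precision:.4f}  macro_recall={self.macro_recall:.4f}  "
            f"misclassified={self.misclassified}"
        )
        return "\n".join(lines)


def train_classifier(train: LabeledFeatures, n_trees: int = 100, seed: int = 0) -> XGBClassifier:
    """Fit the boosted-tree head (one round per tree, single-threaded).

    Rejects single-class training sets: boosting a constant target is
    meaningless and the evaluation metrics would be degenerate.
    """
    y = train.encoded_labels()
    present = np.unique(y)
    if present.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    clf = XGBClassifier(
        n_estimators=n_trees,
        objective="multi:softprob",
        num_class=len(CLASSES),
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    clf.fit(train.features, y)
    return clf


def predict(clf: XGBClassifier, features: np.ndarray) -> list[str]:
    """Predicted class names for a feature matrix."""
    enc = clf.predict(np.asarray(features, dtype=np.float64))
    return [CLASSES[i] for i in enc]


def report_from_confusion(cm: np.ndarray) -> EvalReport:
    """All summary metrics from a confusion matrix (rows=true, cols=pred)."""
    cm = np.asarray(cm)
    if cm.shape != (len(CLASSES), len(CLASSES)) or (cm < 0).any():
        raise ValueError(f"expected a non-negative {len(CLASSES)}x{len(CLASSES)} matrix")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(np.float64)
    pred_pos = cm.sum(axis=0).astype(np.float64)
    true_pos = cm.sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / pred_pos, 0.0)
        recall = np.where(true_pos > 0, tp / true_pos, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2.0 * precision * recall / denom, 0.0)
    return EvalReport(
        confusion=cm.astype(np.int64),
        accuracy=float(tp.sum() / total),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        misclassified=int(total - tp.sum()),
        per_class_f1={c: float(f1[i]) for i, c in enumerate(CLASSES)},
    )


def evaluate(clf: XGBClassifier, test: LabeledFeatures) -> EvalReport:
    """Confusion matrix and macro metrics of a fitted classifier on a test set."""
    if test.features.shape[0] == 0:
        raise ValueError("test set is empty")
    y_true = test.encoded_labels()
    y_pred = clf.predict(test.features)
    cm = confusion_matrix(y_true, y_pred, labels=list(range(len(CLASSES))))
    return report_from_confusion(cm)


def stratified_split(
    features: np.ndarray, labels: list[str], test_fraction: float = 0.2, seed: int = 0
) -> tuple[LabeledFeatures, LabeledFeatures]:
    """Class-stratified train/test split with a fixed seed."""
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=np.asarray(labels)
    )
    features = np.asarray(features, dtype=np.float64)
    return (
        LabeledFeatures(features[train_idx], [labels[i] for i in train_idx], split="train"),
        LabeledFeatures(features[test_idx], [labels[i] for i in test_idx], split="test"),
    )
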