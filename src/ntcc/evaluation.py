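"""Evaluation protocol: stratified k-fold CV, confusion matrices,
per-class precision/recall (on the 0-100 scale), one-vs-rest ROC/AUC,
and feature-set ablation grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classification import ClassifierSpec, FeatureSelection, predict, train


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predicted."""

    counts: np.ndarray
    classes: tuple[int, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class list")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int],
        classes: Optional[Sequence[int]] = None,
    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if classes is None:
            classes = np.unique(np.concatenate([y_true, y_pred]))
        classes = tuple(int(c) for c in classes)
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[index[int(t)], index[int(p)]] += 1
        return cls(counts=counts, classes=classes)


def precision_recall(
    cm: ConfusionMatrix, support: Optional[Sequence[int]] = None
) -> tuple[dict[int, float], dict[int, float], dict[int, bool]]:
    """Per-class precision and recall percentages from a confusion matrix.

    precision_c = 100 * TP_c / (TP_c + FP_c) (column-wise);
    recall_c = 100 * TP_c / (TP_c + FN_c) (row-wise).  A class with no
    predictions has undefined precision; it is recorded as 0 and flagged.

    ``support`` optionally overrides the recall denominators with
    externally known per-class sample counts — used when scoring a
    published confusion matrix whose printed rows do not sum to the
    stated class totals.
    """
    counts = cm.counts
    diag = np.diag(counts).astype(float)
    col = counts.sum(axis=0).astype(float)
    row = counts.sum(axis=1).astype(float) if support is None else np.asarray(
        support, dtype=float)
    precision: dict[int, float] = {}
    recall: dict[int, float] = {}
    undefined: dict[int, bool] = {}
    for i, c in enumerate(cm.classes):
        undefined[c] = col[i] == 0
        precision[c] = 0.0 if col[i] == 0 else 100.0 * diag[i] / col[i]
        recall[c] = 0.0 if row[i] == 0 else 100.0 * diag[i] / row[i]
    return precision, recall, undefined


def roc_auc(
    scores: pd.DataFrame, labels: Sequence[int]
) -> dict[int, Optional[float]]:
    """One-vs-rest AUC per class from continuous scores.

    The ROC is built over all score thresholds and integrated by the
    trapezoidal rule.  A class absent from the labels has undefined AUC
    and is returned as None.
    """
    y = np.asarray(labels)
    out: dict[int, Optional[float]] = {}
    for c in scores.columns:
        c_int = int(c)
        binary = (y == c_int).astype(int)
        if binary.sum() == 0 or binary.sum() == binary.size:
            out[c_int] = None
            continue
        out[c_int] = float(roc_auc_score(binary, scores[c].to_numpy()))
    return out


@dataclass
class EvaluationReport:
    """Metrics of one labeled experiment."""

    confusion: ConfusionMatrix
    precision: dict[int, float]
    recall: dict[int, float]
    precision_undefined: dict[int, bool]
    auc: dict[int, Optional[float]]
    fold_assignment: list[int]
    classifier_id: str
    selection: str
    seed: int
    folds: int

    @property
    def macro_precision(self) -> float:
        return float(np.mean(list(self.precision.values())))

    @property
    def macro_recall(self) -> float:
        return float(np.mean(list(self.recall.values())))

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier_id,
            "selection": self.selection,
            "folds": self.folds,
            "seed": self.seed,
            "classes": list(self.confusion.classes),
            "confusion_matrix": self.confusion.counts.tolist(),
            "precision_pct": {str(k): v for k, v in self.precision.items()},
            "recall_pct": {str(k): v for k, v in self.recall.items()},
            "precision_undefined": {str(k): bool(v) for k, v in
                                    self.precision_undefined.items()},
            "auc": {str(k): v for k, v in self.auc.items()},
            "macro_precision_pct": self.macro_precision,
            "macro_recall_pct": self.macro_recall,
            "fold_assignment": self.fold_assignment,
        }


def kfold_evaluate(
    features: pd.DataFrame,
    labels: Sequence[int],
    spec: ClassifierSpec,
    selection: Optional[FeatureSelection] = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[ConfusionMatrix, EvaluationReport]:
    """Stratified k-fold cross-validation of one classifier config.

    Folds are derived from (labels, k, seed) only.  The scaler is fitted
    inside each training fold — no information leaks from held-out data.
    Held-out predictions are accumulated into one confusion matrix and
    held-out scores are pooled for the one-vs-rest AUCs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    selection = selection or FeatureSelection()
    y = np.asarray(labels)
    classes = tuple(int(c) for c in np.unique(y))

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.full(y.size, -1, dtype=int)
    y_pred = np.empty(y.size, dtype=y.dtype)
    pooled_scores = pd.DataFrame(
        np.zeros((y.size, len(classes))), columns=list(classes)
    )
    for fold, (tr, te) in enumerate(skf.split(np.zeros(y.size), y)):
        fold_of[te] = fold
        model = train(features.iloc[tr], y[tr], spec, selection)
        pred, scores = predict(model, features.iloc[te])
        y_pred[te] = pred
        for c in scores.columns:
            pooled_scores.loc[te, c] = scores[c].to_numpy()

    cm = ConfusionMatrix.from_predictions(y, y_pred, classes=classes)
    prec, rec, undef = precision_recall(cm)
    auc = roc_auc(pooled_scores, y)
    report = EvaluationReport(
        confusion=cm, precision=prec, recall=rec, precision_undefined=undef,
        auc=auc, fold_assignment=fold_of.tolist(),
        classifier_id=spec.id, selection=str(selection), seed=seed, folds=k,
    )
    return cm, report


def ablation_grid(
    features: pd.DataFrame,
    labels: Sequence[int],
    spec: ClassifierSpec,
    selections: Sequence[FeatureSelection],
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-class precision/recall for each feature-set combination.

    Returns a table with one row per selection and per-class
    ``precision_<c>`` / ``recall_<c>`` columns on the 0-100 scale.
    """
    rows = []
    for sel in selections:
        _, report = kfold_evaluate(features, labels, spec, sel, k=k, seed=seed)
        row: dict[str, object] = {"selection": str(sel)}
        for c in report.confusion.classes:
            row[f"precision_{c}"] = report.precision[c]
        for c in report.confusion.classes:
            row[f"recall_{c}"] = report.recall[c]
        rows.append(row)
    return pd.DataFrame(rows).set_index("selection")
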