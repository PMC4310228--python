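"""The seven classifier configurations C1-C7 and their train/predict API.

C1-C4 are support vector machines (linear, quadratic, RBF with
sigma = 10, and sigmoid/MLP kernel), trained one-vs-one as in libsvm;
C5-C7 are feed-forward neural networks with logistic hidden units
(one hidden layer of 10 or 30 nodes, or two layers of 10).  Features
are z-score standardized by default (parameters stored with the model);
an unscaled mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import ALL_SETS, columns_for_sets


@dataclass
class ClassifierSpec:
    """One of the seven classifier configurations.

    ======  =====================================
    id      configuration
    ======  =====================================
    C1      linear-kernel SVM
    C2      quadratic-kernel SVM
    C3      RBF SVM, sigma = 10
    C4      sigmoid (multilayer-perceptron) kernel SVM
    C5      neural network, one hidden layer, 10 nodes
    C6      neural network, one hidden layer, 30 nodes
    C7      neural network, two hidden layers, (10, 10) nodes
    ======  =====================================

    The RBF kernel is exp(-||u-v||^2 / (2 sigma^2)).  SVMs use the
    one-vs-one multiclass scheme (libsvm's native decomposition); the
    networks are natively multinomial.
    """

    id: str
    family: str
    kernel: Optional[str] = None
    rbf_sigma: float = 10.0
    hidden_layers: tuple[int, ...] = ()
    C: float = 1.0
    scale: bool = True
    seed: int = 0
    max_epochs: int = 500

    _SVM_KERNELS = {"linear", "quadratic", "rbf", "mlp"}

    def __post_init__(self) -> None:
        if self.family not in ("svm", "nn"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.family == "svm" and self.kernel not in self._SVM_KERNELS:
            raise ValueError(f"unknown SVM kernel {self.kernel!r}")
        if self.family == "nn" and not self.hidden_layers:
            raise ValueError("nn classifiers need at least one hidden layer")

    @classmethod
    def from_id(cls, cid: str, seed: int = 0, C: float = 1.0,
                scale: bool = True) -> "ClassifierSpec":
        catalog = {
            "C1": dict(family="svm", kernel="linear"),
            "C2": dict(family="svm", kernel="quadratic"),
            "C3": dict(family="svm", kernel="rbf", rbf_sigma=10.0),
            "C4": dict(family="svm", kernel="mlp"),
            "C5": dict(family="nn", hidden_layers=(10,)),
            "C6": dict(family="nn", hidden_layers=(30,)),
            "C7": dict(family="nn", hidden_layers=(10, 10)),
        }
        if cid not in catalog:
            raise ValueError(f"unknown classifier id {cid!r} (expected C1..C7)")
        return cls(id=cid, seed=seed, C=C, scale=scale, **catalog[cid])

    def build_estimator(self, n_features: int):
        if self.family == "svm":
            common = dict(C=self.C, decision_function_shape="ovr",
                          random_state=self.seed)
            if self.kernel == "linear":
                return SVC(kernel="linear", **common)
            if self.kernel == "quadratic":
                return SVC(kernel="poly", degree=2, gamma="scale", coef0=1.0, **common)
            if self.kernel == "rbf":
                gamma = 1.0 / (2.0 * self.rbf_sigma**2)
                return SVC(kernel="rbf", gamma=gamma, **common)
            if self.kernel == "mlp":
                return SVC(kernel="sigmoid", gamma=1.0 / n_features, coef0=0.0,
                           **common)
        return MLPClassifier(
            hidden_layer_sizes=self.hidden_layers,
            activation="logistic",
            max_iter=self.max_epochs,
            random_state=self.seed,
        )


@dataclass
class FeatureSelection:
    """A non-empty subset of the feature sets F1..F7."""

    sets: tuple[str, ...] = ALL_SETS

    def __post_init__(self) -> None:
        sets = tuple(self.sets)
        unknown = set(sets) - set(ALL_SETS)
        if unknown:
            raise ValueError(f"unknown feature sets: {sorted(unknown)}")
        if not sets:
            raise ValueError("feature selection must be non-empty")
        self.sets = sets

    def columns(self, all_columns: Sequence[str]) -> list[str]:
        cols = columns_for_sets(all_columns, self.sets)
        if not cols:
            raise ValueError(f"no columns found for sets {self.sets}")
        return cols

    def __str__(self) -> str:
        return ", ".join(self.sets)


@dataclass
class TrainedModel:
    """A fitted classifier with its scaler and column schema."""

    spec: ClassifierSpec
    selection: FeatureSelection
    columns: list[str]
    scaler: Optional[StandardScaler]
    estimator: object
    classes: np.ndarray = field(default_factory=lambda: np.array([]))

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        return joblib.load(Path(path))


def _design_matrix(features: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    missing = [c for c in columns if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    X = features[list(columns)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [c for c in columns if features[c].isna().any()]
        raise ValueError(f"NaN values in feature columns: {bad}")
    return X


def train(
    features: pd.DataFrame,
    labels: Sequence[int],
    spec: ClassifierSpec,
    selection: Optional[FeatureSelection] = None,
) -> TrainedModel:
    """Fit a classifier on the selected feature-set columns.

    Columns are z-score standardized (parameters stored) unless the
    spec disables scaling.  Deterministic for a given spec seed.
    """
    selection = selection or FeatureSelection()
    y = np.asarray(labels)
    if len(features) != y.size:
        raise ValueError("features and labels must have equal length")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires at least 2 classes")

    cols = selection.columns(features.columns)
    X = _design_matrix(features, cols)
    scaler = None
    if spec.scale:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    est = spec.build_estimator(n_features=X.shape[1])
    est.fit(X, y)
    return TrainedModel(spec=spec, selection=selection, columns=cols,
                        scaler=scaler, estimator=est, classes=classes)


def predict(
    model: TrainedModel, features: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Predict labels and per-class continuous scores.

    Scores are SVM decision values (one-vs-rest aggregation of the
    one-vs-one votes) or network class probabilities; one column per
    training class, suitable for ROC construction.
    """
    X = _design_matrix(features, model.columns)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    est = model.estimator
    labels = est.predict(X)
    if hasattr(est, "decision_function"):
        raw = est.decision_function(X)
        if raw.ndim == 1:  # binary: single margin, expand to two columns
            raw = np.column_stack([-raw, raw])
    else:
        raw = est.predict_proba(X)
    scores = pd.DataFrame(raw, columns=[int(c) for c in est.classes_])
    return np.asarray(labels), scores
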