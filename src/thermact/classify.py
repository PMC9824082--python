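"""Classifier bank and cross-validated model selection.

Four families are supported with defaults matching the reference protocol:
linear-kernel SVM, random forest with 100 trees, 1-nearest-neighbor, and
multinomial logistic regression with an L-BFGS solver.  Model selection uses
stratified K-fold cross-validation (K=10 by default) over a list of
candidate specs, returning the spec with the highest mean validation
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC

from .features import FeatureMatrix

FAMILIES = ("svm", "rf", "knn", "lr")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus hyperparameters.

    Defaults: linear kernel (C=1) for svm, 100 trees for rf, k=1 for knn,
    and the L-BFGS solver for lr.  Multiclass handling is one-vs-rest for
    the linear SVM and native multinomial for LR.
    """

    family: str = "lr"
    params: tuple = ()  # hashable (key, value) pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def describe(self) -> str:
        p = ", ".join(f"{k}={v}" for k, v in self.params)
        return f"{self.family}({p})" if p else self.family


def make_estimator(spec: ClassifierSpec):
    """Instantiate the sklearn estimator behind a spec."""
    p = spec.param_dict
    if spec.family == "svm":
        return LinearSVC(C=p.get("C", 1.0), random_state=spec.seed)
    if spec.family == "rf":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100), random_state=spec.seed
        )
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=p.get("k", 1))
    return LogisticRegression(
        solver="lbfgs", max_iter=p.get("max_iter", 2000), C=p.get("C", 1.0),
        random_state=spec.seed,
    )


@dataclass
class FittedClassifier:
    spec: ClassifierSpec
    estimator: object
    classes: np.ndarray
    n_features: int


def train(spec: ClassifierSpec, features: FeatureMatrix) -> FittedClassifier:
    """Fit one classifier; deterministic given the spec's seed."""
    classes = np.unique(features.labels)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    est = make_estimator(spec)
    est.fit(features.X, features.labels)
    return FittedClassifier(spec, est, classes, features.X.shape[1])


def predict(model: FittedClassifier, features: FeatureMatrix | np.ndarray
            ) -> tuple[np.ndarray, np.ndarray | None]:
    """Predicted labels plus per-class probabilities where available."""
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training ({model.n_features})"
        )
    labels = model.estimator.predict(X)
    scores = None
    if hasattr(model.estimator, "predict_proba"):
        scores = model.estimator.predict_proba(X)
    return labels, scores


def accuracy(model: FittedClassifier, features: FeatureMatrix) -> float:
    labels, _ = predict(model, features)
    return float(np.mean(labels == features.labels))


def confusion(model: FittedClassifier, features: FeatureMatrix) -> pd.DataFrame:
    labels, _ = predict(model, features)
    cm = _sk_confusion(features.labels, labels, labels=model.classes)
    return pd.DataFrame(cm, index=model.classes, columns=model.classes)


def cv_select(
    specs: Sequence[ClassifierSpec],
    features: FeatureMatrix,
    K: int = 10,
    seed: int = 0,
) -> tuple[ClassifierSpec, pd.DataFrame]:
    """Pick the spec with highest mean stratified-CV validation accuracy.

    Returns the winning spec and the full CV table (one row per spec, one
    column per fold plus the mean).  Ties break toward the earlier spec.
    """
    if len(features.X) < K:
        raise ValueError(f"need at least K={K} samples")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    rows = []
    for spec in specs:
        fold_acc = []
        for tr, va in skf.split(features.X, features.labels):
            est = make_estimator(spec)
            est.fit(features.X[tr], features.labels[tr])
            fold_acc.append(float(np.mean(est.predict(features.X[va]) == features.labels[va])))
        rows.append(fold_acc)
    table = pd.DataFrame(
        rows, index=[s.describe() for s in specs],
        columns=[f"fold{i}" for i in range(K)],
    )
    table["mean"] = table.mean(axis=1)
    best = specs[int(np.argmax(table["mean"].to_numpy()))]
    return best, table
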