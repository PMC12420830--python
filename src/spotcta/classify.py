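"""Random-forest cell-type classification over the feature table.

Features are z-scored with training-set statistics ("normalized by mean and
variance") and fed to a random forest; the fitted model carries everything
needed for reproducible prediction: normalization statistics, feature-name
list, class list and the training seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from joblib import dump, load
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)

DEFAULT_CLASSES = ("tumor", "immune", "stroma")

_MODEL_FORMAT_VERSION = 1


class CellTypeClassifier(ClassifierMixin, BaseEstimator):
    """Mean/variance-normalized random-trees cell classifier.

    Parameters
    ----------
    n_estimators : trees in the forest (default 100).
    max_features : features considered per split (default "sqrt").
    random_state : seed; fitting is fully reproducible given it.
    min_per_class : minimum training examples required per class.

    Fitted attributes: ``classes_``, ``feature_names_``, ``mean_``,
    ``scale_`` (constant features get scale 1 and are listed in
    ``constant_features_``), ``forest_``.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_features="sqrt",
        max_depth: int | None = None,
        random_state: int = 0,
        min_per_class: int = 2,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.max_depth = max_depth
        self.random_state = random_state
        self.min_per_class = min_per_class

    def _to_matrix(self, X, fit: bool):
        if isinstance(X, pd.DataFrame):
            if fit:
                names = list(X.columns)
            else:
                missing = [c for c in self.feature_names_ if c not in X.columns]
                if missing:
                    raise ValueError(f"missing model feature columns: {missing}")
                names = self.feature_names_
                X = X[names]
            for c in X.columns:
                if not pd.api.types.is_numeric_dtype(X[c]):
                    raise ValueError(f"non-numeric feature column: '{c}'")
            return X.to_numpy(dtype=float), names
        X = np.asarray(X, dtype=float)
        names = [f"feature_{i}" for i in range(X.shape[1])]
        if not fit and X.shape[1] != len(self.feature_names_):
            raise ValueError("feature count does not match the fitted model")
        return X, names

    def fit(self, X, y):
        Xm, names = self._to_matrix(X, fit=True)
        y = np.asarray(y)
        if pd.isna(y).any():
            raise ValueError("training labels contain missing values")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training set must contain at least 2 classes")
        low = classes[counts < self.min_per_class]
        if len(low):
            raise ValueError(f"classes below min_per_class: {list(low)}")
        if np.isnan(Xm).any():
            raise ValueError("training features contain missing values")

        self.feature_names_ = names
        self.mean_ = Xm.mean(axis=0)
        sd = Xm.std(axis=0, ddof=0)
        self.constant_features_ = [n for n, s in zip(names, sd) if s == 0]
        sd = np.where(sd == 0, 1.0, sd)
        self.scale_ = sd
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            random_state=self.random_state,
        )
        self.forest_.fit((Xm - self.mean_) / self.scale_, y)
        self.classes_ = self.forest_.classes_
        return self

    def transform_features(self, X) -> np.ndarray:
        """Apply the stored z-score normalization (training statistics)."""
        Xm, _ = self._to_matrix(X, fit=False)
        return (Xm - self.mean_) / self.scale_

    def predict_proba(self, X) -> np.ndarray:
        return self.forest_.predict_proba(self.transform_features(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # argmax with alphabetical tie-break: classes_ is sorted, argmax
        # returns the first (alphabetically smallest) maximal class
        order = np.argsort(self.classes_)
        return self.classes_[order][np.argmax(proba[:, order], axis=1)]

    def save(self, path) -> None:
        dump({"format_version": _MODEL_FORMAT_VERSION, "model": self}, path)

    @classmethod
    def load(cls, path) -> "CellTypeClassifier":
        payload = load(path)
        version = payload.get("format_version")
        if version != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version: {version}")
        return payload["model"]


def fit_classifier(features, labels, seed: int = 0, **params) -> CellTypeClassifier:
    """Fit a :class:`CellTypeClassifier` on a training table."""
    return CellTypeClassifier(random_state=seed, **params).fit(features, labels)


def predict_cells(model: CellTypeClassifier, features) -> pd.DataFrame:
    """Predict labels and per-class probabilities for a feature table."""
    proba = model.predict_proba(features)
    labels = model.predict(features)
    index = features.index if isinstance(features, pd.DataFrame) else None
    out = pd.DataFrame(
        proba, columns=[f"p_{c}" for c in model.classes_], index=index
    )
    out.insert(0, "predicted_class", labels)
    return out


def evaluate_classifier(predicted, truth, classes=None) -> dict:
    """Accuracy, per-class precision/recall/F1, and the confusion matrix.

    Confusion rows are truth, columns prediction, ordered by ``classes``
    (default: sorted union of the observed labels).
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = sorted(set(truth) | set(predicted))
    else:
        outside = (set(truth) | set(predicted)) - set(classes)
        if outside:
            raise ValueError(f"labels outside the class set: {sorted(outside)}")
    classes = list(classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, predicted, labels=classes, zero_division=0
    )
    cm = confusion_matrix(truth, predicted, labels=classes)
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=pd.Index(classes, name="class"),
    )
    return {
        "accuracy": accuracy_score(truth, predicted),
        "per_class": per_class,
        "confusion": pd.DataFrame(cm, index=classes, columns=classes),
    }
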