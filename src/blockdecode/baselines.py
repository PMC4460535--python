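"""Baseline classifiers and the common fit/predict adapter surface.

Baselines wrap scikit-learn: one-vs-one multi-class linear SVM with C=1,
Gaussian naive Bayes with per-class per-feature variances, and k-nearest
neighbors with k=6.  The feed-forward net is adapted behind the same
surface so the cross-validation driver is classifier-agnostic.
"""

from __future__ import annotations

import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import nnet
from .dataset import ExampleSet

__all__ = ["baseline_classifiers", "make_classifier", "NNClassifier",
           "SklearnClassifier"]


class SklearnClassifier:
    """Adapter giving sklearn estimators the fit(ExampleSet)/predict contract."""

    def __init__(self, estimator, has_posteriors: bool = False):
        self.estimator = estimator
        self.has_posteriors = has_posteriors
        self.class_order = None

    def fit(self, trainset: ExampleSet, seed: int = 0) -> "SklearnClassifier":
        self.estimator.fit(trainset.X, trainset.y)
        self.class_order = np.asarray(self.estimator.classes_)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.atleast_2d(X)))

    def predict_posteriors(self, X: np.ndarray) -> np.ndarray | None:
        if not self.has_posteriors:
            return None
        return np.asarray(self.estimator.predict_proba(np.atleast_2d(X)))


class NNClassifier:
    """Feed-forward-net adapter; exposes posteriors and the trained net."""

    def __init__(self, val_fraction: float = 0.25,
                 hidden_grid: tuple[int, ...] = nnet.DEFAULT_HIDDEN_GRID,
                 n_restarts: int = nnet.DEFAULT_N_RESTARTS,
                 max_epochs: int = nnet.DEFAULT_MAX_EPOCHS,
                 patience: int = nnet.DEFAULT_PATIENCE):
        self.val_fraction = val_fraction
        self.hidden_grid = tuple(hidden_grid)
        self.n_restarts = n_restarts
        self.max_epochs = max_epochs
        self.patience = patience
        self.has_posteriors = True
        self.net: nnet.TrainedNet | None = None

    def fit(self, trainset: ExampleSet, seed: int = 0) -> "NNClassifier":
        self.net = nnet.train_nn(trainset, val_fraction=self.val_fraction,
                                 hidden_grid=self.hidden_grid,
                                 n_restarts=self.n_restarts, seed=seed,
                                 max_epochs=self.max_epochs, patience=self.patience)
        self.class_order = self.net.class_order
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return nnet.predict_labels(self.net, X)

    def predict_posteriors(self, X: np.ndarray) -> np.ndarray:
        return np.vstack([f.posteriors for f in nnet.predict(self.net, X)])


def baseline_classifiers(name: str, params: dict | None = None):
    """Construct a baseline classifier: svm_linear (C=1, one-vs-one),
    gnb, or knn (k=6)."""
    params = dict(params or {})
    if name == "svm_linear":
        return SklearnClassifier(SVC(kernel="linear",
                                     C=params.pop("C", 1.0),
                                     decision_function_shape="ovo", **params))
    if name == "gnb":
        return SklearnClassifier(GaussianNB(**params), has_posteriors=True)
    if name == "knn":
        return SklearnClassifier(
            KNeighborsClassifier(n_neighbors=params.pop("k", 6), **params),
            has_posteriors=True)
    raise ValueError(f"unknown classifier name: {name!r}")


def make_classifier(spec: str | dict | None):
    """Build a classifier from a spec: a name string, a dict with a
    ``name`` key plus keyword params, or an already-constructed adapter."""
    if spec is None:
        spec = "svm_linear"
    if isinstance(spec, str):
        spec = {"name": spec}
    if isinstance(spec, dict):
        spec = dict(spec)
        name = spec.pop("name")
        if name == "nn":
            return NNClassifier(**spec)
        return baseline_classifiers(name, spec)
    return spec  # already an adapter
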