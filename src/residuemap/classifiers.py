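"""Uniform train/predict interface over the five supervised classifiers.

NB, RF and SVM are delegated to scikit-learn with the published
hyperparameters as defaults; the 1D-CNN and channel-attention 1D-CNN_CA are
the numpy networks from :mod:`residuemap.nn`.  Feature scaling follows the
model family: raw digital numbers go to NB/RF, standardized features (train
mean/sd stored in the model) to SVM and the networks.

Default hyperparameters:

========  ==========================================================
nb        Gaussian, maximum-likelihood priors (no tunables)
rf (OID)  1,411 trees, max depth 281, max_features 'sqrt'
rf (DT1)  1,091 trees, max depth 381, max_features 'auto' (-> sqrt)
svm       RBF kernel, C = 510.0, gamma = 'scale', one-vs-rest
cnn(_ca)  epochs 150, batch 20, lr 0.01, dropout 0.4 (NetworkConfig)
========  ==========================================================
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .calibration import ClassMap
from .multiscale import FeatureStack
from .nn import NetworkConfig, OneDCNNClassifier
from .raster_io import DEFAULT_CLASS_NAMES

METHODS = ("nb", "rf", "svm", "cnn", "cnn_ca")

RF_OID_DEFAULTS: dict = {
    "n_estimators": 1411, "max_depth": 281, "max_features": "sqrt",
}
RF_DT1_DEFAULTS: dict = {
    "n_estimators": 1091, "max_depth": 381, "max_features": "auto",
}
SVM_DEFAULTS: dict = {"C": 510.0, "kernel": "rbf", "gamma": "scale"}
CNN_DEFAULTS: dict = {
    "epochs": 150, "batch_size": 20, "learning_rate": 0.01, "dropout": 0.4,
}

_SCALED_METHODS = ("svm", "cnn", "cnn_ca")


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it to a stack."""

    method: str
    estimator: object
    feature_names: tuple[str, ...]
    classes: np.ndarray
    scaler: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd)
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0
    train_time: float = 0.0

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            mean, sd = self.scaler
            X = (X - mean) / sd
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._prepare(X)))


def _rf_max_features(value):
    # sklearn >= 1.3 dropped the legacy 'auto' alias (sqrt for classifiers)
    return "sqrt" if value == "auto" else value


def _build_estimator(method: str, n_f: int, n_class: int, config, seed: int,
                     variant: str):
    if method == "nb":
        return GaussianNB(), {}
    if method == "rf":
        hp = dict(RF_DT1_DEFAULTS if variant == "dt1" else RF_OID_DEFAULTS)
        if isinstance(config, Mapping):
            hp.update(config)
        est = RandomForestClassifier(
            n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"],
            max_features=_rf_max_features(hp["max_features"]),
            random_state=seed,
            n_jobs=1,
        )
        return est, hp
    if method == "svm":
        hp = dict(SVM_DEFAULTS)
        if isinstance(config, Mapping):
            hp.update(config)
        est = OneVsRestClassifier(
            SVC(C=hp["C"], kernel=hp["kernel"], gamma=hp["gamma"],
                random_state=seed)
        )
        return est, hp
    if method in ("cnn", "cnn_ca"):
        if isinstance(config, NetworkConfig):
            cfg = config
        else:
            params = dict(CNN_DEFAULTS)
            if isinstance(config, Mapping):
                params.update(config)
            cfg = NetworkConfig(n_f=n_f, n_class=n_class, seed=seed, **params)
        from dataclasses import replace

        cfg = replace(cfg, attention=(method == "cnn_ca"))
        return OneDCNNClassifier(cfg), {
            "epochs": cfg.epochs, "batch_size": cfg.batch_size,
            "learning_rate": cfg.learning_rate, "dropout": cfg.dropout,
            "conv_filters": cfg.conv_filters, "dense_widths": cfg.dense_widths,
            "attention": cfg.attention,
        }
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def train_classifier(
    method: str,
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: Sequence[str] | None = None,
    config: Mapping | NetworkConfig | None = None,
    seed: int = 0,
    variant: str = "oid",
) -> TrainedModel:
    """Fit one of the five methods on a per-sample feature table."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("features must be a non-empty (n_samples, n_features) table")
    if not np.isfinite(X).all():
        raise ValueError("features contain NaN or infinite values")
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    n_class = int(np.unique(y).size)
    estimator, hp = _build_estimator(
        method, X.shape[1], n_class, config, seed, variant
    )
    scaler = None
    if method in _SCALED_METHODS:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        scaler = (mean, sd)
        X = (X - mean) / sd
    t0 = time.perf_counter()
    estimator.fit(X, y)
    elapsed = time.perf_counter() - t0
    return TrainedModel(
        method=method,
        estimator=estimator,
        feature_names=tuple(feature_names),
        classes=np.unique(y),
        scaler=scaler,
        hyperparameters=hp,
        seed=seed,
        train_time=elapsed,
    )


@dataclass
class TimingRecord:
    start: float
    end: float

    @property
    def seconds(self) -> float:
        return self.end - self.start


def predict_map(
    model: TrainedModel,
    stack: FeatureStack,
    nodata_mask: np.ndarray | None = None,
    class_names: Mapping[int, str] | None = None,
) -> tuple[ClassMap, TimingRecord]:
    """Classify every pixel of the stack; nodata pixels get label 0."""
    missing = [n for n in model.feature_names if n not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing model features: {missing}")
    r, c = stack.shape
    start = time.perf_counter()
    table = stack.subset(model.feature_names).pixel_table()
    labels = np.zeros(r * c, dtype=np.int64)
    valid = (
        np.ones(r * c, dtype=bool)
        if nodata_mask is None
        else ~np.asarray(nodata_mask).ravel()
    )
    if valid.any():
        labels[valid] = model.predict(table[valid])
    end = time.perf_counter()
    cmap = ClassMap(
        labels.reshape(r, c),
        dict(class_names or DEFAULT_CLASS_NAMES),
        [f"predicted by {model.method} (seed={model.seed})"],
    )
    return cmap, TimingRecord(start, end)
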