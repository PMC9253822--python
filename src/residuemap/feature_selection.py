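"""Gini-importance ranking and incremental feature-subset optimization.

A random forest performs implicit feature selection: the normalized mean
decrease in Gini impurity attributable to each feature layer, averaged over
repeated fits with distinct seeds (ten by default), ranks the layers.  The
optimal image dataset is then found by growing nested subsets in ranking
order (plus any explicitly configured trial subsets, e.g. the spectral-only
baseline), training a classifier on the train split for each, and keeping
the subset with the highest validation kappa (ties: smaller subset, then
lexicographic layer names).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .metrics import evaluate

DEFAULT_N_REPEATS = 10


@dataclass
class ImportanceTable:
    """Mean normalized impurity-decrease importance per feature."""

    feature_names: tuple[str, ...]
    importances: np.ndarray
    n_repeats: int
    seed: int

    def __post_init__(self) -> None:
        self.importances = np.asarray(self.importances, dtype=float)
        if (self.importances < 0).any():
            raise ValueError("importances must be non-negative")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def ranking(self) -> tuple[str, ...]:
        """Feature names by decreasing importance (ties: name order)."""
        order = sorted(
            range(len(self.feature_names)),
            key=lambda i: (-self.importances[i], self.feature_names[i]),
        )
        return tuple(self.feature_names[i] for i in order)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.importances.tolist()))


@dataclass
class SubsetTrial:
    features: tuple[str, ...]
    kappa: float
    oa: float
    model_tag: str


def gini_importance(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: Sequence[str],
    n_repeats: int = DEFAULT_N_REPEATS,
    seed: int = 0,
    n_estimators: int = 200,
) -> ImportanceTable:
    """Mean Gini importance over ``n_repeats`` forest fits with distinct seeds."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("Gini importance needs at least two classes")
    if features.ndim != 2 or features.shape[1] < 1:
        raise ValueError("features must be a (n_samples, n_features) table")
    if features.shape[1] != len(feature_names):
        raise ValueError("feature_names must match the feature table width")
    acc = np.zeros(features.shape[1])
    for rep in range(n_repeats):
        forest = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed + rep, n_jobs=1
        )
        forest.fit(features, labels)
        acc += forest.feature_importances_
    importances = acc / n_repeats
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return ImportanceTable(tuple(feature_names), importances, n_repeats, seed)


def _default_evaluator(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)


def subset_search(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    val_features: np.ndarray,
    val_labels: np.ndarray,
    feature_names: Sequence[str],
    ranking: Sequence[str] | None = None,
    extra_trials: Sequence[Sequence[str]] | None = None,
    estimator_factory: Callable[[int], object] | None = None,
    seed: int = 0,
) -> tuple[list[SubsetTrial], tuple[str, ...]]:
    """Evaluate nested subsets grown in ranking order plus explicit subsets.

    Returns every trial and the argmax-kappa subset (ties broken by smaller
    subset, then lexicographic name order).
    """
    feature_names = tuple(feature_names)
    index = {n: i for i, n in enumerate(feature_names)}
    if ranking is None:
        ranking = gini_importance(
            train_features, train_labels, feature_names, seed=seed
        ).ranking()
    missing = set(feature_names) - set(ranking)
    if missing:
        raise ValueError(f"ranking does not cover features: {sorted(missing)}")
    candidates: list[tuple[str, ...]] = [
        tuple(ranking[: k + 1]) for k in range(len(ranking))
    ]
    for extra in extra_trials or ():
        extra = tuple(extra)
        if not extra:
            raise ValueError("explicit trial subsets must be non-empty")
        if extra not in candidates:
            candidates.append(extra)
    if not candidates:
        raise ValueError("no candidate subsets to evaluate")
    factory = estimator_factory or _default_evaluator
    trials: list[SubsetTrial] = []
    for subset in candidates:
        cols = [index[n] for n in subset]
        est = factory(seed)
        est.fit(train_features[:, cols], train_labels)
        pred = est.predict(val_features[:, cols])
        rep = evaluate(val_labels, pred)
        trials.append(
            SubsetTrial(subset, rep.kappa, rep.oa, type(est).__name__)
        )
    best = min(
        trials,
        key=lambda t: (-t.kappa, len(t.features), tuple(sorted(t.features))),
    )
    return trials, best.features
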