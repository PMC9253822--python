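"""Accuracy assessment: confusion matrix, overall accuracy, Cohen's kappa.

OA is the fraction of correctly predicted validation pixels (trace over
grand total).  Kappa corrects OA for chance agreement
P_k = sum_i (row_i * col_i) / total^2:

    kappa = (OA - P_k) / (1 - P_k)

Time cost (TC) is the wall-clock span of a classification run; it is
reported for context only, never asserted (hardware-dependent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np


@dataclass
class ConfusionMatrix:
    """k x k counts; rows are reference classes, columns predictions."""

    counts: np.ndarray
    class_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.class_ids)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match class_ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    oa: float
    kappa: float
    pe: float                       # chance agreement P_k
    confusion: ConfusionMatrix
    producer_accuracy: Mapping[int, float] = field(default_factory=dict)
    user_accuracy: Mapping[int, float] = field(default_factory=dict)
    tc: float | None = None         # seconds

    def to_dict(self) -> dict:
        return {
            "oa": self.oa,
            "kappa": self.kappa,
            "pe": self.pe,
            "tc": self.tc,
            "class_ids": list(self.confusion.class_ids),
            "confusion": self.confusion.counts.tolist(),
            "producer_accuracy": {str(k): v for k, v in self.producer_accuracy.items()},
            "user_accuracy": {str(k): v for k, v in self.user_accuracy.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def confusion_matrix(
    reference: Sequence[int], predicted: Sequence[int],
    class_ids: Sequence[int] | None = None,
) -> ConfusionMatrix:
    """Tally counts[i][j] = #(reference = class i, predicted = class j)."""
    ref = np.asarray(reference)
    pred = np.asarray(predicted)
    if ref.shape != pred.shape:
        raise ValueError(
            f"reference and predicted lengths differ: {ref.shape} vs {pred.shape}"
        )
    if class_ids is None:
        class_ids = np.unique(np.concatenate([ref, pred]))
    class_ids = tuple(int(c) for c in class_ids)
    index = {c: i for i, c in enumerate(class_ids)}
    k = len(class_ids)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in zip(ref.ravel(), pred.ravel()):
        counts[index[int(a)], index[int(b)]] += 1
    return ConfusionMatrix(counts, class_ids)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def chance_agreement(cm: ConfusionMatrix) -> float:
    """P_k: expected agreement of independent labelings with these margins."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    return float((rows * cols).sum() / cm.total**2)


def kappa(cm: ConfusionMatrix) -> float:
    oa = overall_accuracy(cm)
    pe = chance_agreement(cm)
    if pe >= 1.0:
        raise ValueError("chance agreement is 1 (single occupied cell); kappa undefined")
    return float((oa - pe) / (1.0 - pe))


def per_class_accuracy(cm: ConfusionMatrix) -> tuple[dict[int, float], dict[int, float]]:
    """(producer accuracy by reference class, user accuracy by predicted class)."""
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    diag = np.diag(cm.counts)
    producer = {
        c: float(diag[i] / rows[i]) if rows[i] else float("nan")
        for i, c in enumerate(cm.class_ids)
    }
    user = {
        c: float(diag[i] / cols[i]) if cols[i] else float("nan")
        for i, c in enumerate(cm.class_ids)
    }
    return producer, user


def evaluate(
    reference: Sequence[int], predicted: Sequence[int],
    class_ids: Sequence[int] | None = None, tc: float | None = None,
) -> MetricsReport:
    cm = confusion_matrix(reference, predicted, class_ids)
    producer, user = per_class_accuracy(cm)
    return MetricsReport(
        oa=overall_accuracy(cm),
        kappa=kappa(cm),
        pe=chance_agreement(cm),
        confusion=cm,
        producer_accuracy=producer,
        user_accuracy=user,
        tc=tc,
    )


def time_cost(start: float, end: float) -> float:
    """Elapsed seconds between two timestamps; end must not precede start."""
    if end < start:
        raise ValueError("end timestamp precedes start timestamp")
    return float(end - start)
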