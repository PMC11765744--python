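"""Composite search objective and 3-class diagnostic metrics.

The search objective balances predictive quality against model size:

    fitness = accuracy + depth_penalty * depth - lambda_complexity * n_params

with ``depth_penalty`` negative by default (deeper is costlier) and
``lambda_complexity`` a small per-parameter price.  The optimizer minimizes
``-fitness``.

Diagnostic metrics are per-class one-vs-rest (sensitivity, specificity,
precision, F1) with macro (unweighted) averages, computed from the 3x3
confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = [
    "FitnessWeights",
    "MetricsReport",
    "composite_fitness",
    "confusion_and_metrics",
    "cross_entropy_loss",
]


@dataclass(frozen=True)
class FitnessWeights:
    """Weights of the composite objective (defaults: mild size pressure)."""

    depth_penalty: float = -0.01
    lambda_complexity: float = 1e-8

    def to_dict(self) -> dict:
        return {
            "depth_penalty": self.depth_penalty,
            "lambda_complexity": self.lambda_complexity,
        }


def composite_fitness(
    accuracy: float,
    depth: int,
    complexity: int,
    weights: FitnessWeights = FitnessWeights(),
) -> float:
    """accuracy + depth_penalty*depth - lambda*complexity (maximized)."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be a fraction in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if complexity < 0:
        raise ValueError("complexity (parameter count) must be >= 0")
    return (
        accuracy
        + weights.depth_penalty * depth
        - weights.lambda_complexity * complexity
    )


@dataclass
class MetricsReport:
    """Confusion matrix plus per-class and macro one-vs-rest metrics.

    ``undefined`` lists (class, metric) pairs whose denominator was zero;
    those cells are reported as 0.
    """

    confusion: np.ndarray
    class_names: tuple[str, ...]
    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    undefined: list[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_names": list(self.class_names),
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro": self.macro,
            "undefined": [list(u) for u in self.undefined],
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def confusion_to_csv(self, path: Union[str, Path, None] = None) -> str:
        df = pd.DataFrame(
            self.confusion, index=self.class_names, columns=self.class_names
        )
        if path is not None:
            df.to_csv(path)
        return df.to_csv()


def _safe_div(num: float, den: float, flags: list, cls: str, metric: str) -> float:
    if den == 0:
        flags.append((cls, metric))
        return 0.0
    return num / den


def confusion_and_metrics(
    truth: Sequence[int],
    pred: Sequence[int],
    class_names: Sequence[str] = ("BP", "NL", "VP"),
) -> MetricsReport:
    """Confusion matrix and one-vs-rest metrics for a 3-class problem."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.shape != pred.shape:
        raise ValueError("truth and pred must have equal length")
    n_classes = len(class_names)
    if truth.max() >= n_classes or pred.max() >= n_classes or truth.min() < 0 or pred.min() < 0:
        raise ValueError(f"labels must lie in [0, {n_classes})")

    cm = _sk_confusion_matrix(truth, pred, labels=list(range(n_classes)))
    total = cm.sum()
    accuracy = float(np.trace(cm)) / total

    undefined: list[tuple[str, str]] = []
    per_class: dict[str, dict[str, float]] = {}
    for c, name in enumerate(class_names):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens = _safe_div(tp, tp + fn, undefined, name, "sensitivity")
        spec = _safe_div(tn, tn + fp, undefined, name, "specificity")
        prec = _safe_div(tp, tp + fp, undefined, name, "precision")
        f1 = _safe_div(2 * prec * sens, prec + sens, undefined, name, "f1")
        per_class[name] = {
            "sensitivity": float(sens),
            "specificity": float(spec),
            "precision": float(prec),
            "f1": float(f1),
        }

    macro = {
        metric: float(np.mean([per_class[n][metric] for n in class_names]))
        for metric in ("sensitivity", "specificity", "precision", "f1")
    }
    return MetricsReport(
        cm, tuple(class_names), accuracy, per_class, macro, undefined
    )


def cross_entropy_loss(
    probabilities: Sequence[Sequence[float]],
    truth: Sequence[int],
    eps: float = 1e-12,
) -> float:
    """Mean negative log-probability of the true class (eps-clipped)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth, dtype=int)
    if p.ndim != 2 or len(p) != len(y):
        raise ValueError("probabilities must be (n, n_classes) matching truth")
    if y.min() < 0 or y.max() >= p.shape[1]:
        raise ValueError("labels out of range")
    p_true = np.clip(p[np.arange(len(y)), y], eps, 1.0)
    return float(-np.mean(np.log(p_true)))
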