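"""Evaluation metrics: per-sub-classifier confusion metrics, score errors
(MAE/MSE), the threshold sweep over the PPI call, and percent-change
comparisons between methods.

A metric whose denominator is zero (e.g. precision with no positive calls)
is reported as ``None`` ("NA" in tables), never silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ordinal_head import OrdinalModel, call_ppi, decide_fk, subclassifier_forward


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_calls(cls, predicted, truth) -> "ConfusionCounts":
        p = np.asarray(predicted, dtype=bool)
        t = np.asarray(truth, dtype=bool)
        if p.shape != t.shape:
            raise ValueError("prediction/truth length mismatch")
        return cls(
            tp=int(np.sum(p & t)),
            fp=int(np.sum(p & ~t)),
            tn=int(np.sum(~p & ~t)),
            fn=int(np.sum(~p & t)),
        )


@dataclass(frozen=True)
class ScoreErrors:
    mae: float
    mse: float


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, precision, recall (sensitivity), specificity and F1.

    Undefined ratios are ``None``; F1 is ``None`` if either component is
    undefined or their sum is zero.
    """
    if c.total == 0:
        raise ValueError("no evaluated items")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    f1 = None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "precision": precision,
        "recall": recall,
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "f1": f1,
    }


def score_errors(pred: Sequence[float], truth: Sequence[float]) -> ScoreErrors:
    """Mean absolute and mean squared error between score vectors."""
    p, t = np.asarray(pred, dtype=float), np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred/truth must be equal-length and non-empty")
    d = p - t
    return ScoreErrors(mae=float(np.abs(d).mean()), mse=float((d * d).mean()))


def eval_subclassifier(
    model: OrdinalModel, k: int, encodings: np.ndarray, labels: np.ndarray
) -> dict[str, float | None]:
    """Metrics of the k-th sub-classifier on pre-encoded test pairs.

    Truth is the relabeling y > k; the prediction is decide_fk on the
    sub-classifier's softmax outputs.
    """
    if not 1 <= k <= model.partition.K - 1:
        raise ValueError(f"k must be in 1..{model.partition.K - 1}")
    s1, s2 = subclassifier_forward(np.atleast_2d(encodings), model.heads[k - 1])
    predicted = np.asarray(decide_fk(s1, s2)) > 0
    truth = np.asarray(labels) > k
    return confusion_metrics(ConfusionCounts.from_calls(predicted, truth))


def threshold_sweep(
    pred_scores: Sequence[float],
    true_scores: Sequence[float],
    thetas: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
) -> pd.DataFrame:
    """Five metrics of the thresholded PPI call at each theta.

    Both the call and its ground truth apply the same strict threshold
    (interaction <=> confidence score > theta). Rows are ordered by theta.
    """
    pred = np.asarray(pred_scores, dtype=float)
    true = np.asarray(true_scores, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("pred/true length mismatch")
    rows = []
    for theta in sorted(thetas):
        c = ConfusionCounts.from_calls(call_ppi(pred, theta), call_ppi(true, theta))
        m = confusion_metrics(c)
        rows.append(
            {
                "theta": theta,
                "positives": int(c.tp + c.fp),
                **{name: (np.nan if v is None else v) for name, v in m.items()},
            }
        )
    return pd.DataFrame(rows)


def percent_change(reference: float, new: float) -> float:
    """Percent reduction of ``new`` relative to ``reference``:
    100 * (reference - new) / reference."""
    if reference == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * (reference - new) / reference


def format_metric(value: float | None, decimals: int = 4) -> str:
    return "NA" if value is None else f"{value:.{decimals}f}"
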