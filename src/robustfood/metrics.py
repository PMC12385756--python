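"""Evaluation metrics: top-k accuracy, per-class precision/recall/F1,
macro-F1, and multi-seed mean +/- SD aggregation.

Score ties are broken deterministically toward the lowest class index
(stable sort), so rankings are reproducible across platforms. Classes with
zero support and zero predictions get F1 = 0 and are flagged. Run summaries
use the sample (n-1) standard deviation, matching the usual "mean +/- SD
over five seeds" reporting convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvalRecord",
    "ClassScoresTable",
    "RunSummary",
    "rank_scores",
    "top_k_accuracy",
    "per_class_scores",
    "aggregate_runs",
]


@dataclass
class EvalRecord:
    """True labels plus, per sample, class indices ranked by descending score."""

    true_labels: np.ndarray          # (N,)
    ranked_predictions: np.ndarray   # (N, k) distinct class indices

    def __post_init__(self):
        self.true_labels = np.asarray(self.true_labels, dtype=np.int64)
        self.ranked_predictions = np.asarray(self.ranked_predictions, dtype=np.int64)
        if self.ranked_predictions.ndim != 2 or \
                self.ranked_predictions.shape[0] != self.true_labels.shape[0]:
            raise ValueError("ranked_predictions must be (N, k) aligned with labels")

    @classmethod
    def from_scores(cls, true_labels, scores) -> "EvalRecord":
        return cls(np.asarray(true_labels), rank_scores(scores))

    @property
    def n_samples(self) -> int:
        return self.true_labels.shape[0]


def rank_scores(scores: np.ndarray) -> np.ndarray:
    """Class indices sorted by descending score; ties -> lowest index first."""
    scores = np.asarray(scores, dtype=np.float64)
    return np.argsort(-scores, axis=-1, kind="stable")


@dataclass
class ClassScoresTable:
    """Per-class confusion counts and scores from top-1 predictions."""

    classes: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    zero_support: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def rows(self) -> list[dict]:
        return [
            {"class": int(c), "TP": int(tp), "FP": int(fp), "FN": int(fn),
             "precision": float(p), "recall": float(r), "f1": float(f)}
            for c, tp, fp, fn, p, r, f in zip(
                self.classes, self.tp, self.fp, self.fn,
                self.precision, self.recall, self.f1)
        ]


@dataclass
class RunSummary:
    mean: float
    sd: float
    values: np.ndarray

    def __str__(self) -> str:
        return f"{self.mean:.4f} +/- {self.sd:.4f} (n={len(self.values)})"


def top_k_accuracy(rec: EvalRecord, k: int) -> float:
    """Fraction of samples whose true label is among the top-k predictions."""
    if rec.n_samples == 0:
        raise ValueError("empty evaluation record")
    if k < 1:
        raise ValueError("k must be >= 1")
    if rec.ranked_predictions.shape[1] < k:
        raise ValueError(f"rankings have only {rec.ranked_predictions.shape[1]} "
                         f"entries, need k={k}")
    hits = (rec.ranked_predictions[:, :k] == rec.true_labels[:, None]).any(axis=1)
    return float(hits.mean())


def per_class_scores(rec: EvalRecord, n_classes: int | None = None) -> ClassScoresTable:
    """TP/FP/FN and precision/recall/F1 per class from top-1 predictions;
    macro-F1 is the unweighted mean over classes."""
    if rec.n_samples == 0:
        raise ValueError("empty evaluation record")
    y = rec.true_labels
    yhat = rec.ranked_predictions[:, 0]
    if n_classes is None:
        n_classes = int(max(y.max(), yhat.max())) + 1
    classes = np.arange(n_classes)
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    for c in classes:
        tp[c] = int(((y == c) & (yhat == c)).sum())
        fp[c] = int(((y != c) & (yhat == c)).sum())
        fn[c] = int(((y == c) & (yhat != c)).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    zero_support = (tp + fn == 0) & (tp + fp == 0)
    if zero_support.any():
        warnings.warn(
            f"classes {classes[zero_support].tolist()} have no true or predicted "
            "instances; their F1 is defined as 0", stacklevel=2)
    return ClassScoresTable(classes=classes, tp=tp, fp=fp, fn=fn,
                            precision=precision, recall=recall, f1=f1,
                            macro_f1=float(f1.mean()), zero_support=zero_support)


def aggregate_runs(values) -> RunSummary:
    """Mean and sample (n-1) standard deviation over independent runs."""
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.ndim != 1 or vals.shape[0] < 2:
        raise ValueError("aggregate_runs needs >= 2 run values; "
                         "report single runs explicitly")
    return RunSummary(mean=float(vals.mean()),
                      sd=float(vals.std(ddof=1)),
                      values=vals)
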