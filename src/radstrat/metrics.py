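"""Evaluation measures: ROC AUC and class-specific precision/recall/F.

A classifier emits one high-risk score per patient; every measure here
derives from that single score vector.  AUC is the rank statistic (the
probability that a random high-risk patient outscores a random lower-risk
one, ties credited 0.5).  Class-specific precision, recall and F1 come
from one binarization of the scores: a patient is called high-risk iff
score >= threshold, and the lower-risk prediction is its complement, so
both classes' metrics derive from the same thresholding.

``fmax_sweep`` scans every achievable threshold and reports the maximum F
for the target class (F_max) together with the precision (P_max), recall
(R_max) and threshold at the maximum — the quantities used both to rank
candidate classifiers and to set the final classifier's operating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import InvalidInputError, UndefinedMetricError

CLASSES = ("high", "lower")

#: The seven evaluation measures used throughout the framework.
MEASURES = (
    "auc",
    "high_fmax",
    "high_pmax",
    "high_rmax",
    "lower_fmax",
    "lower_pmax",
    "lower_rmax",
)


@dataclass(frozen=True)
class PredictionSet:
    """Per-sample high-risk scores paired with true labels."""

    scores: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise InvalidInputError("scores and labels must be equal-length 1D arrays")
        if not np.all(np.isfinite(scores)):
            raise InvalidInputError("scores must be finite")
        bad = set(labels) - set(CLASSES)
        if bad:
            raise InvalidInputError(f"unknown labels {bad}; expected {CLASSES}")
        ids = self.sample_ids
        if ids is not None:
            ids = np.asarray(ids, dtype=object)
            if ids.shape != scores.shape:
                raise InvalidInputError("sample_ids length mismatch")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", ids)

    def __len__(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class ThresholdedMetrics:
    """Best-F operating point for one target class."""

    f_max: float
    p_max: float
    r_max: float
    threshold_star: float
    target_class: str


@dataclass(frozen=True)
class EvaluationResult:
    """AUC plus the per-class best-F operating points."""

    auc: float
    high: ThresholdedMetrics
    lower: ThresholdedMetrics

    def measure(self, name: str) -> float:
        """Look up one of the seven canonical measures by name."""
        if name == "auc":
            return self.auc
        cls, stat = name.split("_")
        tm: ThresholdedMetrics = getattr(self, cls)
        return {"fmax": tm.f_max, "pmax": tm.p_max, "rmax": tm.r_max}[stat]


def _require_both_classes(preds: PredictionSet) -> None:
    present = set(preds.labels)
    if present != set(CLASSES):
        raise UndefinedMetricError(
            f"both classes required, got labels {sorted(map(str, present))}"
        )


def roc_auc(preds: PredictionSet) -> float:
    """Rank-statistic AUC: P(score_high > score_lower) + 0.5 P(tie)."""
    _require_both_classes(preds)
    pos = preds.labels == "high"
    ranks = rankdata(preds.scores)
    n_pos = int(pos.sum())
    n_neg = len(preds) - n_pos
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f


def confusion_prf(
    predicted: np.ndarray, labels: np.ndarray, target_class: str
) -> tuple[float, float, float]:
    """Precision, recall, F1 of hard class predictions for one target class.

    Zero-denominator cases (no predicted positives, or P = R = 0) are
    defined as 0.
    """
    predicted = np.asarray(predicted, dtype=object)
    labels = np.asarray(labels, dtype=object)
    pred_pos = predicted == target_class
    is_pos = labels == target_class
    tp = int((pred_pos & is_pos).sum())
    fp = int((pred_pos & ~is_pos).sum())
    fn = int((~pred_pos & is_pos).sum())
    return _prf(tp, fp, fn)


def binarize(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Hard labels from high-risk scores: high iff score >= threshold."""
    return np.where(np.asarray(scores, dtype=float) >= threshold, "high", "lower").astype(object)


def prf_at(
    preds: PredictionSet, threshold: float, target_class: str
) -> tuple[float, float, float]:
    """Precision, recall and F for one class at one score threshold.

    High-risk is predicted iff score >= threshold; the lower-risk
    prediction is the complement of the same binarization.
    """
    if target_class not in CLASSES:
        raise InvalidInputError(f"target_class must be one of {CLASSES}")
    return confusion_prf(binarize(preds.scores, threshold), preds.labels, target_class)


def fmax_sweep(preds: PredictionSet, target_class: str) -> ThresholdedMetrics:
    """Best-F operating point over all achievable thresholds.

    Candidate thresholds are the distinct score values plus the endpoints
    0 and 1 (the all-positive and, for the lower-risk class, all-negative
    binarizations).  Ties on F break toward the lowest threshold.
    """
    _require_both_classes(preds)
    candidates = np.unique(np.concatenate([preds.scores, [0.0, 1.0]]))
    best = None
    for t in candidates:
        p, r, f = prf_at(preds, float(t), target_class)
        if best is None or f > best[0] + 1e-15:
            best = (f, p, r, float(t))
    f, p, r, t = best
    return ThresholdedMetrics(f, p, r, t, target_class)


def evaluate(preds: PredictionSet) -> EvaluationResult:
    """AUC plus the F_max operating points of both classes."""
    return EvaluationResult(
        auc=roc_auc(preds),
        high=fmax_sweep(preds, "high"),
        lower=fmax_sweep(preds, "lower"),
    )


def evaluate_at(preds: PredictionSet, threshold: float) -> dict[str, float]:
    """The seven validation measures at a *fixed* operating threshold.

    AUC still ranks by the continuous scores; the per-class precision,
    recall and F come from the single binarization at ``threshold``.
    Keys mirror :data:`MEASURES` with ``f``/``p``/``r`` in place of the
    ``max`` suffix at the fixed threshold.
    """
    _require_both_classes(preds)
    hard = binarize(preds.scores, threshold)
    out = {"auc": roc_auc(preds)}
    for cls in CLASSES:
        p, r, f = confusion_prf(hard, preds.labels, cls)
        out[f"{cls}_f"] = f
        out[f"{cls}_p"] = p
        out[f"{cls}_r"] = r
    return out
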