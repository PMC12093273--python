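"""Evaluation metrics for each pipeline stage.

Classification: accuracy, sensitivity, specificity from confusion counts,
plus rank-based (Mann-Whitney) AUC.  Segmentation: Dice similarity and the
average Euclidean distance over threshold-matched centroid pairs.
Detection: precision / recall / F1 from matched counts.

A note on the detection formulas: the source convention this package follows
*as printed* defines precision = NTP / NGT and recall = NTP / Ndetected,
which swaps the roles the two names conventionally have.  Both conventions
are exposed via the ``convention`` argument ("as_printed" default,
"conventional" for the usual definitions); F1, being the harmonic mean, is
identical under either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import match as _match


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; the value is undefined, not 0."""


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("at least one observation required")


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)."""
    total = c.tp + c.tn + c.fp + c.fn
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive cases")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative cases")
    return {
        "accuracy": (c.tp + c.tn) / total,
        "sensitivity": c.tp / (c.tp + c.fn),
        "specificity": c.tn / (c.tn + c.fp),
    }


def auc(scores, labels) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties 1/2.

    Computed from midranks (the Mann-Whitney U statistic), which equals
    trapezoidal ROC integration.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: both classes must be present")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores), dtype=float)
    sorted_scores = scores[order]
    i = 0
    rank = 1
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        midrank = (rank + rank + (j - i)) / 2.0
        ranks[order[i:j + 1]] = midrank
        rank += j - i + 1
        i = j + 1
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def dice(st: np.ndarray, sg: np.ndarray) -> float:
    """Dice similarity 2|St ∩ Sg| / (|St| + |Sg|).

    `st` is the automatic segmentation, `sg` the ground truth.  Defined as
    1.0 when both masks are empty (nothing to segment, nothing segmented).
    """
    st = np.asarray(st).astype(bool)
    sg = np.asarray(sg).astype(bool)
    if st.shape != sg.shape:
        raise ValueError("masks must share a shape")
    denom = int(st.sum()) + int(sg.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((st & sg).sum()) / denom


def avg_euclidean_distance(gt, pred, diff: float = 10.0) -> float:
    """Mean Euclidean distance over centroid pairs matched within `diff`.

    Matching is the same distance-thresholded unique matching used for
    detection.  Raises when no pair matches (mean of zero pairs is
    undefined).
    """
    if diff <= 0:
        raise ValueError("diff must be positive")
    m = _match(gt, pred, threshold=diff)
    if m.n_tp == 0:
        raise UndefinedMetricError("no matched points within the threshold")
    return float(np.mean(m.distances))


def detection_metrics(n_gt: int, n_tp: int, n_detected: int,
                      convention: str = "as_printed") -> dict[str, float]:
    """Precision / recall / F1 from matched-detection counts.

    "as_printed": precision = NTP/NGT, recall = NTP/Ndetected.
    "conventional": precision = NTP/Ndetected, recall = NTP/NGT.
    F1 = harmonic mean, identical in both conventions.
    """
    if convention not in ("as_printed", "conventional"):
        raise ValueError("convention must be 'as_printed' or 'conventional'")
    if n_tp > min(n_gt, n_detected):
        raise ValueError("NTP cannot exceed NGT or Ndetected")
    if n_gt == 0 or n_detected == 0:
        raise UndefinedMetricError("NGT and Ndetected must be positive")
    per_gt = n_tp / n_gt
    per_det = n_tp / n_detected
    if convention == "as_printed":
        precision, recall = per_gt, per_det
    else:
        precision, recall = per_det, per_gt
    f1 = 0.0 if (precision + recall) == 0 else \
        2.0 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1,
            "convention": convention}
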