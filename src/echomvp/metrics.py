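"""Evaluation metrics at frame, cardiac-cycle, patient and pixel level.

Frame- and patient-level classification is scored with precision and recall
of the positive class, macro-averaged F1 and accuracy.  Cycle-level phase
detection is scored with AccSys = T / (P + N - T), where N is the number of
ground-truth systole periods, P the number of predicted systole periods and
T the number of ground-truth cycles hit by at least one predicted systolic
frame.  Frame placement of end-diastole (ED) and end-systole (ES) within
matched cycles is scored with the average absolute frame error (AE) and the
fractions of matched cycles with error <= 1 (E1) and <= 2 (E2).  Pixel
overlap is scored with Dice and IoU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

from .data import DataError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationScores",
    "CycleMatchSummary",
    "PhaseErrorStats",
    "SegOverlap",
    "classification_metrics",
    "accsys",
    "match_cycles",
    "phase_error_stats",
    "overlap_metrics",
]


@dataclass
class ClassificationScores:
    precision: float
    recall: float
    f1: float  # macro average over both classes
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
        }


@dataclass
class CycleMatchSummary:
    """Cycle detection counts: T correct out of P predicted and N true cycles."""

    t_correct: int
    p_predicted: int
    n_truth: int

    def __post_init__(self) -> None:
        if not 0 <= self.t_correct <= min(self.p_predicted, self.n_truth):
            raise ValidationError("cycle counts must satisfy 0 <= T <= min(P, N)")


@dataclass
class PhaseErrorStats:
    errors: np.ndarray  # absolute frame errors, one per matched cycle
    ae: float
    e1: float
    e2: float


@dataclass
class SegOverlap:
    dice: float
    iou: float


def classification_metrics(truth, predicted, positive_label=1) -> ClassificationScores:
    """Precision/recall of the positive class, macro F1 and accuracy.

    Precision with zero predicted positives is reported as 0 with a logged
    warning rather than raising; degenerate all-negative predictors occur
    with stub models.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1:
        raise ValidationError("truth and prediction must be equal-length 1-D sequences")
    if truth.size == 0:
        raise ValidationError("empty label sequences")
    pos_pred = predicted == positive_label
    if not pos_pred.any():
        logger.warning("no positive predictions; precision reported as 0")
    precision = _skm.precision_score(
        truth, predicted, pos_label=positive_label, zero_division=0
    )
    recall = _skm.recall_score(truth, predicted, pos_label=positive_label, zero_division=0)
    f1 = _skm.f1_score(truth, predicted, average="macro", zero_division=0)
    accuracy = _skm.accuracy_score(truth, predicted)
    return ClassificationScores(float(precision), float(recall), float(f1), float(accuracy))


def _as_periods(cycles) -> list[tuple[int, int]]:
    """Accept a CyclePrediction or a plain list of (start, end) pairs."""
    periods = getattr(cycles, "systole_periods", cycles)
    return [(int(a), int(b)) for a, b in periods]


def match_cycles(gt_cycles, pred_cycles) -> tuple[CycleMatchSummary, list[tuple[int, int]]]:
    """Greedy temporal matching of predicted systole periods to true cycles.

    A ground-truth cycle counts as correctly detected when at least one
    predicted-systolic frame falls inside its systole period; each predicted
    period may validate at most one ground-truth cycle, assigned greedily in
    temporal order so one long predicted period cannot validate several
    cycles.  Returns the count summary and the list of matched index pairs
    (gt_index, pred_index).
    """
    gt = _as_periods(gt_cycles)
    pred = _as_periods(pred_cycles)
    pairs: list[tuple[int, int]] = []
    next_pred = 0
    for gi, (gs, ge) in enumerate(gt):
        for pi in range(next_pred, len(pred)):
            ps, pe = pred[pi]
            if ps <= ge and pe >= gs:  # inclusive interval overlap
                pairs.append((gi, pi))
                next_pred = pi + 1
                break
            if ps > ge:
                break
    summary = CycleMatchSummary(len(pairs), len(pred), len(gt))
    return summary, pairs


def accsys(gt_cycles, pred_cycles) -> tuple[CycleMatchSummary, float]:
    """Cycle-level detection accuracy AccSys = T / (P + N - T)."""
    summary, _ = match_cycles(gt_cycles, pred_cycles)
    t, p, n = summary.t_correct, summary.p_predicted, summary.n_truth
    if p == 0 and n == 0:
        raise DataError("AccSys undefined with no predicted and no true cycles")
    return summary, t / (p + n - t)


def phase_error_stats(gt_frames, pred_frames) -> PhaseErrorStats:
    """AE / E1 / E2 over matched ED (or ES) frame index pairs."""
    gt_frames = np.asarray(gt_frames, dtype=float)
    pred_frames = np.asarray(pred_frames, dtype=float)
    if gt_frames.shape != pred_frames.shape:
        raise ValidationError("matched frame lists must have equal length")
    if gt_frames.size == 0:
        raise DataError("no matched cycles: frame error statistics undefined")
    errors = np.abs(pred_frames - gt_frames)
    return PhaseErrorStats(
        errors=errors,
        ae=float(errors.mean()),
        e1=float((errors <= 1).mean()),
        e2=float((errors <= 2).mean()),
    )


def overlap_metrics(pred_mask, truth_mask) -> SegOverlap:
    """Dice and IoU of two binary masks.

    Both-empty masks score dice = iou = 1 by convention; in the evaluation
    protocol every scored frame contains a prolapse region, so the
    convention only matters for degenerate synthetic inputs.
    """
    pred_mask = np.asarray(pred_mask).astype(bool)
    truth_mask = np.asarray(truth_mask).astype(bool)
    if pred_mask.shape != truth_mask.shape:
        raise ValidationError("masks must share a shape")
    inter = int(np.logical_and(pred_mask, truth_mask).sum())
    a, b = int(pred_mask.sum()), int(truth_mask.sum())
    if a + b == 0:
        return SegOverlap(dice=1.0, iou=1.0)
    dice = 2.0 * inter / (a + b)
    iou = inter / (a + b - inter)
    return SegOverlap(dice=float(dice), iou=float(iou))
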