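"""Segmentation evaluation: IoU, average precision, mask correlation and
spindle-chromosome perpendicularity QC."""

from __future__ import annotations

import numpy as np

from .geometry import Ellipse2D, eccentricity

__all__ = [
    "MatchResult",
    "UndefinedMetricError",
    "iou",
    "average_precision",
    "mask_correlation",
    "perpendicularity",
    "ERROR_CATEGORIES",
]

# Expert error-classification taxonomy for manual segmentation review reports.
# Documentation constants only; no automatic classifier is provided.
ERROR_CATEGORIES = {
    "U-Minor": "minor undersegmentation",
    "U-Major": "major undersegmentation",
    "O-Minor": "minor oversegmentation",
    "O-Major": "major oversegmentation",
    "MO": "missed object",
}


class UndefinedMetricError(ValueError):
    """Metric undefined for the given input (e.g. no ground truth)."""


class MatchResult:
    """IoU of a prediction/truth pair with threshold and class agreement."""

    def __init__(self, iou: float, matched: bool, class_agreement: bool):
        if not 0.0 <= iou <= 1.0:
            raise ValueError("iou must lie in [0, 1]")
        self.iou = iou
        self.matched = matched
        self.class_agreement = class_agreement


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; 1.0 when both are empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def average_precision(predictions: list, truths: list, iou_threshold: float = 0.5) -> float:
    """All-points average precision over a score-ranked precision-recall sweep.

    ``predictions`` are (mask, score) pairs or scored candidates with ``mask``
    and ``score`` attributes; ``truths`` are binary masks. Predictions are
    swept in descending score order, each greedily matched to the unconsumed
    truth of highest IoU >= iou_threshold, and

        AP = sum_n (R_n - R_{n-1}) P_n .

    Raises
    ------
    UndefinedMetricError
        If no ground truths are given.
    """
    if not truths:
        raise UndefinedMetricError("average precision undefined without ground truths")
    pairs = []
    for p in predictions:
        if hasattr(p, "mask"):
            pairs.append((np.asarray(p.mask).astype(bool), float(p.score)))
        else:
            mask, score = p
            pairs.append((np.asarray(mask).astype(bool), float(score)))
    pairs.sort(key=lambda ms: -ms[1])
    truth_masks = [np.asarray(t).astype(bool) for t in truths]
    consumed = [False] * len(truth_masks)
    tp, fp = 0, 0
    ap = 0.0
    prev_recall = 0.0
    n_truth = len(truth_masks)
    for mask, _score in pairs:
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truth_masks):
            if consumed[j]:
                continue
            v = iou(mask, t)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            consumed[best_j] = True
            tp += 1
        else:
            fp += 1
        recall = tp / n_truth
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return float(ap)


def mask_correlation(auto: np.ndarray, manual: np.ndarray) -> float:
    """Pearson correlation of two flattened binary masks (phi coefficient).

    Quantifies human-vs-automated segmentation agreement pixelwise.

    Raises
    ------
    UndefinedMetricError
        For constant masks (zero variance).
    """
    a = np.asarray(auto).astype(bool)
    m = np.asarray(manual).astype(bool)
    if a.shape != m.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {m.shape}")
    af = a.ravel().astype(float)
    mf = m.ravel().astype(float)
    if af.std() == 0 or mf.std() == 0:
        raise UndefinedMetricError("correlation undefined for a constant mask")
    return float(np.corrcoef(af, mf)[0, 1])


def perpendicularity(spindle_ellipse: Ellipse2D, chromosome_ellipse: Ellipse2D, warn_ecc: float = 0.1):
    """Acute angle (degrees, [0, 90]) between the two major axes.

    90 deg indicates a chromosome plate perfectly perpendicular to the spindle
    long axis. Returns (angle, warning) where warning is a message when either
    ellipse is too circular (eccentricity < warn_ecc) for its orientation to
    be meaningful, else None.
    """
    diff = abs(spindle_ellipse.angle_deg - chromosome_ellipse.angle_deg) % 180.0
    angle = 180.0 - diff if diff > 90.0 else diff
    warning = None
    low = [
        name
        for name, e in (("spindle", spindle_ellipse), ("chromosome", chromosome_ellipse))
        if eccentricity(e) < warn_ecc
    ]
    if low:
        warning = f"orientation poorly defined for near-circular ellipse(s): {', '.join(low)}"
    return float(angle), warning
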