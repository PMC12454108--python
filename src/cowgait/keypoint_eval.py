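"""Keypoint localisation metrics: PCK and threshold-averaged AP / AR.

A predicted keypoint is correct at normalised threshold t when its
Euclidean distance to the ground truth is at most t * max(H, W) of the
heatmap extent.  PCK is the fraction correct at one threshold; AP and
AR average precision and recall over a ladder of thresholds.  In the
fixed-set pose setting every annotated keypoint has exactly one
prediction, so FP = FN per threshold and AP = AR unless a visibility
mask removes points from one side.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pck", "ap_ar", "default_threshold_ladder"]


def default_threshold_ladder() -> np.ndarray:
    """Correctness thresholds used for AP/AR averaging.

    The conventional 0.50-0.95 (step 0.05) strictness ladder scaled into
    normalised-distance thresholds relative to the 0.05 reference, i.e.
    0.025 ... 0.0475.
    """
    return 0.05 * np.arange(0.50, 0.951, 0.05)


def _distances(pred, gt) -> np.ndarray:
    pred = np.asarray(pred, dtype=float).reshape(-1, 2)
    gt = np.asarray(gt, dtype=float).reshape(-1, 2)
    if pred.shape != gt.shape:
        raise ValueError("predicted and ground-truth sets differ in length")
    if pred.shape[0] == 0:
        raise ValueError("empty keypoint set")
    return np.linalg.norm(pred - gt, axis=1)


def pck(pred, gt, heatmap_hw: tuple[int, int], t: float) -> float:
    """Fraction of keypoints within t * max(H, W) of the ground truth."""
    if t <= 0:
        raise ValueError("threshold must be positive")
    H, W = heatmap_hw
    if H <= 0 or W <= 0:
        raise ValueError("heatmap extent must be positive")
    dist = _distances(pred, gt)
    return float((dist <= t * max(H, W)).mean())


def ap_ar(
    pred,
    gt,
    heatmap_hw: tuple[int, int],
    thresholds=None,
    visibility=None,
) -> tuple[float, float]:
    """Average precision and recall across correctness thresholds.

    At each threshold a prediction within range of its ground-truth
    point is a TP; a visible prediction outside range is an FP; a
    visible ground-truth point with no correct prediction is an FN.
    ``visibility`` optionally masks annotated-but-invisible points out
    of both sets.
    """
    if thresholds is None:
        thresholds = default_threshold_ladder()
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("need at least one threshold")
    H, W = heatmap_hw
    dist = _distances(pred, gt)
    if visibility is not None:
        visibility = np.asarray(visibility, dtype=bool)
        if visibility.shape != dist.shape:
            raise ValueError("visibility mask length mismatch")
        dist = dist[visibility]
        if dist.size == 0:
            raise ValueError("no visible keypoints")
    precisions, recalls = [], []
    for t in thresholds:
        correct = dist <= t * max(H, W)
        tp = int(correct.sum())
        fp = int((~correct).sum())
        fn = int((~correct).sum())
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
    return float(np.mean(precisions)), float(np.mean(recalls))
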