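"""Segmentation quality metrics: mean accuracy, mean IoU and Boundary F1.

All three scores are two-class (background, lesion) and live in [0, 1]:

* ``mean_acc`` — class-balanced pixel accuracy: for each class, the fraction
  of that class's ground-truth pixels predicted correctly (per-class recall),
  averaged over the classes present in the ground truth.
* ``mean_iou`` — per-class intersection-over-union averaged over both
  classes; a class absent from both prediction and ground truth is skipped.
* ``bf1`` — Boundary F1: precision is the fraction of predicted boundary
  pixels within Euclidean distance theta of some ground-truth boundary pixel,
  recall the converse, and BF1 their harmonic mean.  Boundaries are the
  8-connected mask contours; theta defaults to 0.75% of the image diagonal
  (rounded up, at least 1 px), the customary tolerance for this score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .._util import as_binary_mask
from ..edge import extract_edge


@dataclass
class SegMetrics:
    mean_acc: float
    mean_iou: float
    bf1: float

    def as_tuple(self):
        return (self.mean_acc, self.mean_iou, self.bf1)


def default_boundary_tolerance(shape) -> int:
    """0.75% of the image diagonal, rounded up to at least 1 px."""
    diag = float(np.hypot(*shape))
    return max(1, int(np.ceil(0.0075 * diag)))


def boundary_f1(pred, gt, theta: float | None = None) -> float:
    """Boundary F1 between two binary masks at distance tolerance ``theta``."""
    p = as_binary_mask(pred)
    g = as_binary_mask(gt)
    if p.shape != g.shape:
        raise ValueError("pred and gt must share a shape")
    if theta is None:
        theta = default_boundary_tolerance(p.shape)
    bp = extract_edge(p)
    bg = extract_edge(g)
    if not bp.any() and not bg.any():
        return 1.0
    if not bp.any() or not bg.any():
        return 0.0
    # distance of every pixel to the nearest boundary pixel of the other mask
    dist_to_gt = ndimage.distance_transform_edt(~bg)
    dist_to_pred = ndimage.distance_transform_edt(~bp)
    precision = float((dist_to_gt[bp] <= theta).mean())
    recall = float((dist_to_pred[bg] <= theta).mean())
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def seg_metrics(pred, gt, theta: float | None = None) -> SegMetrics:
    """Mean accuracy, mean IoU and BF1 of a predicted mask vs ground truth."""
    p = as_binary_mask(pred)
    g = as_binary_mask(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")

    accs, ious = [], []
    for cls in (False, True):
        pc = p == cls
        gc = g == cls
        n_gt = int(gc.sum())
        if n_gt > 0:
            accs.append(float((pc & gc).sum() / n_gt))
        union = int((pc | gc).sum())
        if union > 0:
            ious.append(float((pc & gc).sum() / union))
    return SegMetrics(
        mean_acc=float(np.mean(accs)) if accs else 1.0,
        mean_iou=float(np.mean(ious)) if ious else 1.0,
        bf1=boundary_f1(p, g, theta),
    )
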