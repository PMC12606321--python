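"""Lesion localisation and detection evaluation.

The detector contract is a plain callable ``detect(image) -> list[Detection]``
so a learned backend can be plugged in; the reference implementation shipped
here is classical and fully deterministic: the smooth anatomical background is
flattened by subtracting a heavily blurred copy, the residual is lightly
smoothed and thresholded by Otsu's method (excluding the left calibration
strip, which contains the scale bar rather than anatomy), and the largest
connected component's bounding box is returned with its solidity as the
confidence score.

Boxes are 0-based, half-open ``[row0, row1) x [col0, col1)``.  Evaluation is
single-class mean average precision at IoU 0.5 with all-point interpolation
of the precision-recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure as skmeasure


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open in both axes."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self):
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError(f"degenerate box {self}")

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    @property
    def area(self) -> int:
        return self.height * self.width

    def as_tuple(self):
        return (self.row0, self.col0, self.row1, self.col1)


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")


def pad_box(box: BoundingBox, padding: int, image_shape) -> BoundingBox:
    """Extend each side by ``padding`` pixels, clipped to the image bounds.

    Fixed padding around the detected box preserves contour context for the
    segmentation stage (default 25 px at pipeline level).
    """
    if padding < 0:
        raise ValueError("padding must be >= 0")
    h, w = image_shape[:2]
    return BoundingBox(
        row0=max(0, box.row0 - padding),
        col0=max(0, box.col0 - padding),
        row1=min(h, box.row1 + padding),
        col1=min(w, box.col1 + padding),
    )


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; disjoint boxes give 0."""
    ir0 = max(a.row0, b.row0)
    ic0 = max(a.col0, b.col0)
    ir1 = min(a.row1, b.row1)
    ic1 = min(a.col1, b.col1)
    inter = max(0, ir1 - ir0) * max(0, ic1 - ic0)
    if inter == 0:
        return 0.0
    union = a.area + b.area - inter
    return inter / union


def mask_bounding_box(mask: np.ndarray) -> BoundingBox:
    """Tightest half-open box around the foreground of a boolean mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return BoundingBox(int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)


def detect_reference(image, exclude_left_fraction: float = 0.10) -> list[Detection]:
    """Classical single-lesion detector for bright blob-like lesions.

    Background-subtracted Otsu thresholding followed by largest connected
    component; the leftmost strip (scale bar region) is excluded.  Returns an
    empty list when no component is found.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_reference expects a 2-D grayscale image")
    h, w = img.shape
    strip = int(np.floor(exclude_left_fraction * w))
    body = img[:, strip:]
    # flatten the smooth anatomical background, then denoise the residual
    background = ndimage.gaussian_filter(body, sigma=max(h, w) / 8.0)
    residual = ndimage.gaussian_filter(body - background, sigma=2.0)
    if np.ptp(residual) < 1e-6:  # flat image (up to filter roundoff)
        return []
    try:
        thr = filters.threshold_otsu(residual)
    except ValueError:  # constant residual
        return []
    # Otsu can split inside the background mode when the lesion covers only a
    # tiny pixel fraction; never threshold below 3 robust sigma of the residual
    mad = np.median(np.abs(residual - np.median(residual)))
    thr = max(thr, 3.0 * 1.4826 * mad)
    fg = residual > thr
    if not fg.any():
        return []
    labels = skmeasure.label(fg, connectivity=2)
    props = skmeasure.regionprops(labels)
    best = max(props, key=lambda p: p.area)
    if best.area < 9:  # noise speckle, not a lesion
        return []
    r0, c0, r1, c1 = best.bbox
    score = float(np.clip(best.solidity, 0.0, 1.0))
    box = BoundingBox(r0, c0 + strip, r1, c1 + strip)
    return [Detection(box=box, score=score)]


def map_at_50(
    detections: Sequence[Sequence[Detection]],
    ground_truth: Sequence[Sequence[BoundingBox]],
    iou_threshold: float = 0.5,
) -> float:
    """Single-class average precision at the given IoU threshold.

    ``detections[i]`` and ``ground_truth[i]`` belong to image ``i``.
    Detections are sorted by descending score and greedily matched to the
    unmatched ground-truth box of highest IoU; a match below the threshold is
    a false positive.  The PR curve is integrated with all-point
    interpolation (area under the precision envelope).
    """
    if len(detections) != len(ground_truth):
        raise ValueError("detections and ground_truth must cover the same images")
    n_gt = sum(len(g) for g in ground_truth)
    if n_gt == 0:
        raise ValueError("no ground-truth boxes: AP is undefined")

    flat = [
        (det.score, img_idx, det.box)
        for img_idx, dets in enumerate(detections)
        for det in dets
    ]
    flat.sort(key=lambda t: -t[0])
    matched = [np.zeros(len(g), dtype=bool) for g in ground_truth]
    tp = np.zeros(len(flat))
    fp = np.zeros(len(flat))
    for k, (_, img_idx, box) in enumerate(flat):
        gts = ground_truth[img_idx]
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if matched[img_idx][j]:
                continue
            v = iou(box, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            tp[k] = 1
            matched[img_idx][best_j] = True
        else:
            fp[k] = 1
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(fp)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)

    # all-point interpolation: integrate the precision envelope over recall
    r = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(np.diff(r) > 0)[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))
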