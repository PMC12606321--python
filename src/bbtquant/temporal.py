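"""Longitudinal comparison of lesion masks across visits.

Serial radiographs of the same benign lesion are compared by (a) a
quantitative area criterion and (b) a qualitative shape overlay:

* Area changes are computed in mm^2 (each visit keeps its own calibration,
  since the scale bar may differ between acquisitions) both between
  consecutive visits and against the baseline visit; any absolute change
  greater than the clinical-significance threshold (default 10%) is flagged,
  whether growth or shrinkage.
* For shape comparison, each visit's mask is translated — integer pixels
  only, no resampling, so pixel areas and contours are preserved exactly —
  so that its foreground centroid lands on the centre of a common canvas,
  and the contours are overlaid in per-visit colours (red, green, blue in
  time order).  Shape change is left to expert judgement: the overlay and
  the XOR area are reported, never auto-classified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import as_binary_mask
from .edge import extract_edge
from .measure import Measurement, measure
from .scalebar import Calibration

DEFAULT_COLORS = ((255, 0, 0), (0, 255, 0), (0, 0, 255))


@dataclass
class ChangeThreshold:
    """Clinical-significance threshold on |area change| in percent."""

    pct: float = 10.0

    def __post_init__(self):
        if self.pct <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class AreaChange:
    """Percent area change between two timepoints, with its flag."""

    from_idx: int
    to_idx: int
    pct_change: float
    flagged: bool
    kind: str  # 'consecutive' or 'baseline'


@dataclass
class SeriesComparison:
    measurements: list[Measurement]
    centroids: list[tuple[float, float]]
    aligned_masks: list[np.ndarray]
    changes: list[AreaChange]
    overlay: np.ndarray
    colors: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def any_flagged(self) -> bool:
        return any(c.flagged for c in self.changes)


def centroid(mask) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the foreground pixel coordinates."""
    m = as_binary_mask(mask)
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise ValueError("empty mask has no centroid")
    return float(rows.mean()), float(cols.mean())


def align(masks, margin: int = 4) -> list[np.ndarray]:
    """Recentre each mask on a common canvas by integer translation.

    The canvas is sized to hold the largest recentred mask plus ``margin``;
    every mask is shifted by the integer offset that brings its centroid
    closest to the canvas centre (within 0.5 px in each axis).  Relative
    scale is untouched — no resampling, so areas are preserved exactly.
    """
    masks = [as_binary_mask(m) for m in masks]
    if len(masks) < 2:
        raise ValueError("need at least two masks to align")
    cents = [centroid(m) for m in masks]
    half_r = half_c = 0
    for m, (cr, cc) in zip(masks, cents):
        rows, cols = np.nonzero(m)
        half_r = max(half_r, int(np.ceil(max(rows.max() - cr, cr - rows.min()))))
        half_c = max(half_c, int(np.ceil(max(cols.max() - cc, cc - cols.min()))))
    H = 2 * (half_r + margin) + 1
    W = 2 * (half_c + margin) + 1
    center = (H // 2, W // 2)
    aligned = []
    for m, (cr, cc) in zip(masks, cents):
        rows, cols = np.nonzero(m)
        dr = int(np.round(center[0] - cr))
        dc = int(np.round(center[1] - cc))
        canvas = np.zeros((H, W), dtype=bool)
        canvas[rows + dr, cols + dc] = True
        aligned.append(canvas)
    return aligned


def area_change(
    measurements: list[Measurement], threshold: ChangeThreshold | float = ChangeThreshold()
) -> list[AreaChange]:
    """Percent area changes, consecutive and vs baseline, with flags.

    Percent change from reference r to timepoint t is
    ``100 * (area_t - area_r) / area_r``; a change is flagged iff its
    absolute value exceeds the threshold (strictly greater).
    """
    if isinstance(threshold, (int, float)):
        threshold = ChangeThreshold(float(threshold))
    if len(measurements) < 2:
        raise ValueError("need at least two timepoints")
    areas = [m.area_mm2 for m in measurements]
    if areas[0] <= 0:
        raise ValueError("baseline area must be positive")
    changes = []
    for i in range(1, len(areas)):
        if areas[i - 1] <= 0:
            raise ValueError(f"zero area at timepoint {i - 1}")
        pct = 100.0 * (areas[i] - areas[i - 1]) / areas[i - 1]
        changes.append(
            AreaChange(i - 1, i, pct, abs(pct) > threshold.pct, "consecutive")
        )
    for i in range(2, len(areas)):
        pct = 100.0 * (areas[i] - areas[0]) / areas[0]
        changes.append(AreaChange(0, i, pct, abs(pct) > threshold.pct, "baseline"))
    return changes


def overlay_contours(aligned_masks, colors=DEFAULT_COLORS) -> np.ndarray:
    """Additively blend each mask's contour in its visit colour.

    Overlapping contour pixels add channel-wise (saturating at 255), so e.g.
    coincident red and green contours appear yellow.  If there are more masks
    than colours the palette cycles, with a warning.
    """
    masks = [as_binary_mask(m) for m in aligned_masks]
    if not masks:
        raise ValueError("no masks to overlay")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("aligned masks must share one canvas shape")
    if len(masks) > len(colors):
        warnings.warn("more masks than colours: palette will cycle", stacklevel=2)
    out = np.zeros(shape + (3,), dtype=np.uint16)
    for k, m in enumerate(masks):
        col = np.asarray(colors[k % len(colors)], dtype=np.uint16)
        e = extract_edge(m)
        out[e] += col
    return np.clip(out, 0, 255).astype(np.uint8)


def xor_area_mm2(mask_a, mask_b, calibration: Calibration) -> float:
    """Area (mm^2) of the symmetric difference of two aligned masks."""
    a = as_binary_mask(mask_a)
    b = as_binary_mask(mask_b)
    return float(np.logical_xor(a, b).sum()) * calibration.mm_per_px**2


def compare_series(
    masks,
    calibrations,
    threshold: ChangeThreshold | float = ChangeThreshold(),
    colors=DEFAULT_COLORS,
) -> SeriesComparison:
    """Full longitudinal comparison of one lesion across ordered visits."""
    if len(masks) != len(calibrations):
        raise ValueError("one calibration per mask required")
    measurements = [measure(m, c) for m, c in zip(masks, calibrations)]
    cents = [centroid(m) for m in masks]
    aligned = align(masks)
    changes = area_change(measurements, threshold)
    ov = overlay_contours(aligned, colors)
    used = [tuple(colors[k % len(colors)]) for k in range(len(masks))]
    return SeriesComparison(
        measurements=measurements,
        centroids=cents,
        aligned_masks=aligned,
        changes=changes,
        overlay=ov,
        colors=used,
    )
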