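"""Physical lesion size and area from a mask plus a calibration.

Linear size comes from the minimum axis-aligned bounding box of the lesion
mask, with inclusive pixel extents (a single-pixel lesion is 1 px wide, the
same semantics as a physical bar of n pixels):

    width_mm  = W_pixels * S        height_mm = H_pixels * S

where S is the calibration's millimetres per pixel.  Area comes from the
pixel count of the mask, not the box:

    area_mm2 = N_pixels * S**2

which avoids the overestimation a width x height product commits on
irregular or asymmetric lesions.  Deviation reports compare predicted and
expert ground-truth tables case by case; percent deviations are computed
from the unrounded absolute deviations and only rounded (half-up, two
decimals) for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_binary_mask, round_half_up
from .detection import BoundingBox
from .scalebar import Calibration


@dataclass
class Measurement:
    """Pixel and millimetre measurements of one lesion mask."""

    W_pixels: int
    H_pixels: int
    width_mm: float
    height_mm: float
    N_pixels: int
    area_mm2: float
    calibration: Calibration | None = None

    def to_dict(self) -> dict:
        d = {
            "W_pixels": self.W_pixels,
            "H_pixels": self.H_pixels,
            "width_mm": self.width_mm,
            "height_mm": self.height_mm,
            "N_pixels": self.N_pixels,
            "area_mm2": self.area_mm2,
        }
        if self.calibration is not None:
            d["calibration"] = self.calibration.to_dict()
        return d


def min_bounding_box(mask) -> BoundingBox:
    """Tightest axis-aligned box enclosing the mask foreground (half-open)."""
    m = as_binary_mask(mask)
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return BoundingBox(int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)


def size_mm(box: BoundingBox, calibration: Calibration) -> tuple[float, float]:
    """(width_mm, height_mm) of a box under the calibration; exact products."""
    s = calibration.mm_per_px
    return box.width * s, box.height * s


def area_mm2(mask, calibration: Calibration) -> float:
    """Mask pixel count times the physical area of one pixel (mm^2)."""
    m = as_binary_mask(mask)
    n = int(m.sum())
    if n == 0:
        warnings.warn("empty mask: area is 0", stacklevel=2)
        return 0.0
    return n * calibration.mm_per_px**2


def measure(mask, calibration: Calibration) -> Measurement:
    """Full measurement of one lesion mask under one calibration."""
    m = as_binary_mask(mask)
    box = min_bounding_box(m)
    w_mm, h_mm = size_mm(box, calibration)
    n = int(m.sum())
    return Measurement(
        W_pixels=box.width,
        H_pixels=box.height,
        width_mm=w_mm,
        height_mm=h_mm,
        N_pixels=n,
        area_mm2=n * calibration.mm_per_px**2,
        calibration=calibration,
    )


@dataclass
class DeviationReport:
    """Case-by-case and aggregate deviation of predicted vs ground-truth sizes.

    ``per_case`` holds one row per case with absolute (mm, rounded 2 dp for
    display) and percent deviations per axis; the aggregates are recomputable
    from the unrounded per-case percent deviations.
    """

    per_case: pd.DataFrame
    mean_pct_width: float
    mean_pct_height: float
    overall_mean_pct: float
    max_pct: float
    max_case: int
    max_axis: str
    _raw_pct: pd.DataFrame = field(repr=False, default=None)


def deviation_report(pred: pd.DataFrame, gt: pd.DataFrame) -> DeviationReport:
    """Build a deviation report from paired (width_mm, height_mm) tables.

    Both tables must have columns ``width_mm`` and ``height_mm`` and equal
    length; rows are paired positionally.  Percent deviation of axis a in
    case i is ``100 * |pred_ia - gt_ia| / gt_ia``.
    """
    for name, df in (("pred", pred), ("gt", gt)):
        missing = {"width_mm", "height_mm"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")
    if len(pred) != len(gt):
        raise ValueError(f"length mismatch: {len(pred)} pred vs {len(gt)} gt")
    gt_w = np.asarray(gt["width_mm"], dtype=float)
    gt_h = np.asarray(gt["height_mm"], dtype=float)
    if (gt_w <= 0).any() or (gt_h <= 0).any():
        raise ValueError("ground-truth sizes must be positive")
    abs_w = np.abs(np.asarray(pred["width_mm"], dtype=float) - gt_w)
    abs_h = np.abs(np.asarray(pred["height_mm"], dtype=float) - gt_h)
    pct_w = 100.0 * abs_w / gt_w
    pct_h = 100.0 * abs_h / gt_h

    per_case = pd.DataFrame(
        {
            "case": np.arange(1, len(gt_w) + 1),
            "abs_dev_width_mm": round_half_up(abs_w, 2),
            "abs_dev_height_mm": round_half_up(abs_h, 2),
            "pct_dev_width": round_half_up(pct_w, 2),
            "pct_dev_height": round_half_up(pct_h, 2),
        }
    )
    all_pct = np.concatenate([pct_w, pct_h])
    axes = np.array(["width"] * len(pct_w) + ["height"] * len(pct_h))
    k = int(np.argmax(all_pct))
    return DeviationReport(
        per_case=per_case,
        mean_pct_width=round_half_up(pct_w.mean(), 2),
        mean_pct_height=round_half_up(pct_h.mean(), 2),
        overall_mean_pct=round_half_up(all_pct.mean(), 2),
        max_pct=round_half_up(all_pct[k], 2),
        max_case=int(k % len(pct_w)) + 1,
        max_axis=str(axes[k]),
        _raw_pct=pd.DataFrame({"pct_dev_width": pct_w, "pct_dev_height": pct_h}),
    )
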