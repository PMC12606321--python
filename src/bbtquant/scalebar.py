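"""Scale-bar detection and pixel-to-millimetre calibration.

Radiographs carry a burned-in vertical scale bar near the left edge together
with a printed physical length (e.g. "13 cm").  Calibration proceeds as:

1. isolate the leftmost fraction of the image (default 10%),
2. binarise the strip at a fixed intensity threshold (default 25: values
   <= 25 become background, > 25 foreground),
3. pick the 8-connected component with the greatest vertical height — that
   is the bar, and its pixel height is the bar length in pixels,
4. read the printed label with an OCR backend and parse "<number> <cm|mm>"
   into millimetres.

The spatial resolution is then ``mm_per_px = bar_length_mm / bar_height_px``.
Both that ratio and its reciprocal are stored explicitly: physical size and
area computations always use millimetres per pixel, while the conventional
two-decimal report figure (``report_ratio``) is pixels per millimetre, which
is how worked examples in clinical reports are usually printed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from skimage import measure as skmeasure

from ._util import round_half_up, truncate
from .ocr import OcrBackend, TemplateOcr


class CalibrationError(RuntimeError):
    """Base class for calibration failures."""


class ScaleBarNotFound(CalibrationError):
    """No foreground component in the calibration strip."""


class OcrFailure(CalibrationError):
    """OCR produced no parsable length label."""


@dataclass
class Calibration:
    """Pixel <-> millimetre conversion derived from the scale bar."""

    bar_height_px: int
    bar_length_mm: float
    ocr_text: str = ""
    rounding: str = "round"  # report_ratio rounding mode: 'round' | 'truncate'

    def __post_init__(self):
        if self.bar_height_px <= 0 or self.bar_length_mm <= 0:
            raise ValueError("bar height and length must be positive")
        if self.rounding not in ("round", "truncate"):
            raise ValueError("rounding must be 'round' or 'truncate'")

    @property
    def mm_per_px(self) -> float:
        return self.bar_length_mm / self.bar_height_px

    @property
    def px_per_mm(self) -> float:
        return self.bar_height_px / self.bar_length_mm

    @property
    def report_ratio(self) -> float:
        """px/mm rounded to two decimals — the conventional report figure."""
        if self.rounding == "truncate":
            return truncate(self.px_per_mm, 2)
        return round_half_up(self.px_per_mm, 2)

    def to_dict(self) -> dict:
        return {
            "bar_height_px": self.bar_height_px,
            "bar_length_mm": self.bar_length_mm,
            "mm_per_px": self.mm_per_px,
            "px_per_mm": self.px_per_mm,
            "report_ratio": self.report_ratio,
            "ocr_text": self.ocr_text,
            "rounding": self.rounding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(
            bar_height_px=int(d["bar_height_px"]),
            bar_length_mm=float(d["bar_length_mm"]),
            ocr_text=d.get("ocr_text", ""),
            rounding=d.get("rounding", "round"),
        )


def extract_roi(image, fraction: float = 0.10) -> np.ndarray:
    """Return the leftmost ``floor(fraction * width)`` columns of the image."""
    img = np.asarray(image)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ncols = int(np.floor(fraction * img.shape[1]))
    if ncols < 1:
        raise ValueError("ROI fraction yields zero columns")
    return img[:, :ncols]


def binarize(strip, threshold: int = 25) -> np.ndarray:
    """Fixed-threshold binarisation: intensity <= threshold -> 0, else 1."""
    return np.asarray(strip) > threshold


def tallest_component(binary) -> tuple[np.ndarray, int]:
    """Select the 8-connected component with the greatest vertical extent.

    Height is the inclusive row extent (max row - min row + 1).  Ties are
    broken by leftmost minimum column, then by largest pixel area.
    """
    b = np.asarray(binary).astype(bool)
    labels = skmeasure.label(b, connectivity=2)
    props = skmeasure.regionprops(labels)
    if not props:
        raise ScaleBarNotFound("no foreground component in calibration strip")
    best = max(props, key=lambda p: (p.bbox[2] - p.bbox[0], -p.bbox[1], p.area))
    height = best.bbox[2] - best.bbox[0]
    return labels == best.label, int(height)


_SCALE_RE = re.compile(r"(\d+(?:\.\d+)?)\s*(cm|mm)", re.IGNORECASE)


def parse_scale_text(text: str) -> float:
    """Parse a label like ``"13 cm"`` or ``"100mm"`` into millimetres."""
    if not text:
        raise OcrFailure("empty OCR text")
    m = _SCALE_RE.search(text)
    if m is None:
        raise OcrFailure(f"no parsable length in OCR text {text!r}")
    value = float(m.group(1))
    unit = m.group(2).lower()
    return value * 10.0 if unit == "cm" else value


def calibrate(
    image,
    ocr_backend: OcrBackend | None = None,
    roi_fraction: float = 0.10,
    threshold: int = 25,
    rounding: str = "round",
) -> Calibration:
    """Full calibration: ROI -> binarise -> tallest component + OCR -> ratio.

    Bar-detection failure raises :class:`ScaleBarNotFound`; a detected bar
    with an unreadable label raises :class:`OcrFailure` (distinct, so the
    caller can degrade to pixel-unit reporting and say why).
    """
    if ocr_backend is None:
        ocr_backend = TemplateOcr(threshold=threshold)
    strip = extract_roi(image, roi_fraction)
    binary = binarize(strip, threshold)
    _, height_px = tallest_component(binary)
    results = ocr_backend.recognize(strip)
    text = " ".join(r.text for r in results)
    length_mm = parse_scale_text(text)
    return Calibration(
        bar_height_px=height_px,
        bar_length_mm=length_mm,
        ocr_text=text,
        rounding=rounding,
    )
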