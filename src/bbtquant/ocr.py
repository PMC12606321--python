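"""OCR backends for reading the scale-bar label.

The backend contract is ``recognize(image) -> list[OcrResult]``.  Two
backends are provided:

* :class:`TemplateOcr` — a deterministic exact-template matcher for the
  package's built-in 5x7 bitmap font.  It recognises anything rendered by the
  phantom generator and is the backend used throughout the test suite.
* :class:`EasyOcrAdapter` — a thin adapter around the ``easyocr`` engine for
  real radiographs.  The engine is an optional runtime dependency; the
  adapter raises a clear error at construction when it is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from skimage import measure as skmeasure

from . import _font
from .detection import BoundingBox


@dataclass
class OcrResult:
    text: str
    box: BoundingBox
    confidence: float

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be in [0, 1]")


@runtime_checkable
class OcrBackend(Protocol):
    def recognize(self, image: np.ndarray) -> list[OcrResult]: ...


class TemplateOcr:
    """Exact template matching against the built-in bitmap font.

    Connected components small enough to be glyphs are cropped to their tight
    bounding boxes and compared bit-for-bit against the tight font templates
    at the known rendering scale.  Components that match no template (e.g.
    the scale bar itself, or noise specks) are ignored.  Glyphs are ordered
    left to right; a horizontal gap wider than one character cell inserts a
    space.
    """

    def __init__(self, threshold: int = 25, scale: int = _font.GLYPH_SCALE):
        self.threshold = threshold
        self.scale = scale
        self._templates = {ch: _font.tight_glyph(ch) for ch in _font.GLYPHS}

    def recognize(self, image: np.ndarray) -> list[OcrResult]:
        img = np.asarray(image)
        binary = img > self.threshold
        if not binary.any():
            return []
        s = self.scale
        labels = skmeasure.label(binary, connectivity=2)
        glyphs = []
        for prop in skmeasure.regionprops(labels):
            r0, c0, r1, c1 = prop.bbox
            if (r1 - r0) > 7 * s or (c1 - c0) > 5 * s:
                continue  # too large to be a glyph (the bar, typically)
            patch = labels[r0:r1, c0:c1] == prop.label
            ch = self._match(patch)
            if ch is not None:
                glyphs.append((r0, c0, r1, c1, ch))
        if not glyphs:
            return []
        glyphs.sort(key=lambda g: g[1])
        text = []
        prev_c1 = None
        for r0, c0, r1, c1, ch in glyphs:
            if prev_c1 is not None and (c0 - prev_c1) > _font.CELL_WIDTH * s:
                text.append(" ")
            text.append(ch)
            prev_c1 = c1
        box = BoundingBox(
            min(g[0] for g in glyphs),
            min(g[1] for g in glyphs),
            max(g[2] for g in glyphs),
            max(g[3] for g in glyphs),
        )
        return [OcrResult(text="".join(text), box=box, confidence=1.0)]

    def _match(self, patch: np.ndarray) -> str | None:
        s = self.scale
        if patch.shape[0] % s or patch.shape[1] % s:
            return None
        # collapse the rendering scale back to font cells
        small = patch.reshape(
            patch.shape[0] // s, s, patch.shape[1] // s, s
        ).any(axis=(1, 3))
        for ch, tmpl in self._templates.items():
            if small.shape == tmpl.shape and np.array_equal(small, tmpl):
                return ch
        return None


class EasyOcrAdapter:
    """Adapter exposing the ``easyocr`` engine through the backend contract."""

    def __init__(self, languages=("en",)):
        try:
            import easyocr
        except ImportError as exc:  # pragma: no cover - optional engine
            raise ImportError(
                "EasyOcrAdapter requires the optional 'easyocr' package; "
                "install it or use TemplateOcr for phantom images"
            ) from exc
        self._reader = easyocr.Reader(list(languages), gpu=False)

    def recognize(self, image: np.ndarray) -> list[OcrResult]:  # pragma: no cover
        results = []
        for quad, text, conf in self._reader.readtext(np.asarray(image)):
            rows = [p[1] for p in quad]
            cols = [p[0] for p in quad]
            box = BoundingBox(
                int(min(rows)), int(min(cols)), int(max(rows)) + 1, int(max(cols)) + 1
            )
            results.append(OcrResult(text=text, box=box, confidence=float(conf)))
        return results
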