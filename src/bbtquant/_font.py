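"""Built-in 5x7 bitmap font for scale-bar labels.

Using a fixed bitmap font (rather than a system font) makes phantom rendering
byte-reproducible across machines and lets the fixture OCR backend recognise
glyphs by exact template matching.  Glyphs are rendered at an integer scale
factor (default 2, i.e. 10x14 px) so they stay well below the 20 px minimum
bar height and the bar is always the tallest component in the strip.
"""

from __future__ import annotations

import numpy as np

GLYPH_SCALE = 2  # rendering magnification of the 5x7 cells
CELL_WIDTH = 6  # horizontal advance per character, in font cells

_GLYPHS_RAW = {
    "0": ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    "1": ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    "2": ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    "3": ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    "4": ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    "5": ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    "6": ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    "7": ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    "8": ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    "9": ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
    "c": ("00000", "00000", "01110", "10000", "10000", "10001", "01110"),
    "m": ("00000", "00000", "11010", "10101", "10101", "10101", "10101"),
    ".": ("00000", "00000", "00000", "00000", "00000", "01100", "01100"),
}

GLYPHS: dict[str, np.ndarray] = {
    ch: np.array([[c == "1" for c in row] for row in rows], dtype=bool)
    for ch, rows in _GLYPHS_RAW.items()
}


def tight_glyph(ch: str) -> np.ndarray:
    """Glyph bitmap cropped to its tight bounding box (for template matching)."""
    g = GLYPHS[ch]
    rows = np.nonzero(g.any(axis=1))[0]
    cols = np.nonzero(g.any(axis=0))[0]
    return g[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]


def text_extent(text: str, scale: int = GLYPH_SCALE) -> tuple[int, int]:
    """(height, width) in pixels of rendered ``text``."""
    return 7 * scale, max(0, (CELL_WIDTH * len(text) - 1) * scale)


def render_text(text: str, scale: int = GLYPH_SCALE, value: int = 255) -> np.ndarray:
    """Render ``text`` into a fresh uint8 image (background 0).

    Unknown characters (including space) advance the pen without drawing.
    """
    h, w = text_extent(text, scale)
    out = np.zeros((h, max(w, 1)), dtype=np.uint8)
    x = 0
    for ch in text:
        g = GLYPHS.get(ch.lower())
        if g is not None:
            big = np.repeat(np.repeat(g, scale, axis=0), scale, axis=1)
            out[: 7 * scale, x : x + 5 * scale][big] = value
        x += CELL_WIDTH * scale
    return out
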