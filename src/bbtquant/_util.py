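"""Small shared helpers: rounding and binary-mask coercion."""

from __future__ import annotations

import numpy as np


def round_half_up(x, ndigits: int = 0):
    """Round with ties going away from zero-half upward (0.5 -> 1, 127.5 -> 128).

    numpy/python round() uses banker's rounding; reported millimetre values and
    8-bit channel intensities here use conventional half-up instead.
    """
    x = np.asarray(x, dtype=float)
    scale = 10.0**ndigits
    out = np.floor(x * scale + 0.5) / scale
    if out.ndim == 0:
        return float(out)
    return out


def truncate(x, ndigits: int = 0):
    """Truncate toward zero at the given number of decimals."""
    scale = 10.0**ndigits
    return float(np.trunc(float(x) * scale) / scale)


def as_binary_mask(mask) -> np.ndarray:
    """Coerce an array to a boolean mask, rejecting non-binary values.

    Accepts bool arrays, {0, 1} integer label masks and {0, 255} PNG-style
    masks.  Anything else raises ``ValueError`` rather than silently
    thresholding.
    """
    a = np.asarray(mask)
    if a.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {a.shape}")
    if a.dtype == bool:
        return a
    vals = np.unique(a)
    if np.isin(vals, (0, 1)).all():
        return a.astype(bool)
    if np.isin(vals, (0, 255)).all():
        return a > 0
    raise ValueError(f"mask is not binary (values {vals[:10]})")
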