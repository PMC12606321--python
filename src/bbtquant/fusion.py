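"""Wavelet channel fusion of lesion crops.

A single-level orthonormal 2-D Haar transform splits a grayscale crop into
four half-resolution subbands: the approximation LL and three detail bands.
On each non-overlapping 2x2 block ``[[a, b], [c, d]]``::

    LL = (a + b + c + d) / 2      approximation
    LH = ((a + b) - (c + d)) / 2  vertical detail   (responds to horizontal edges)
    HL = ((a + c) - (b + d)) / 2  horizontal detail (responds to vertical edges)
    HH = (a - b - c + d) / 2      diagonal detail

The subband naming convention varies between libraries; this module fixes it
algebraically by the closed form above and records it in the channel map so
downstream consumers cannot be bitten by a silent swap.

The fusion image maps LL to the red channel, LH to green and HL to blue
(the diagonal band HH is treated as noise and discarded), each band
independently min-max rescaled to 8 bits.  Stacked with the original
grayscale crop this yields the 4-channel input used by the segmentation
ablation: intensity, structure, and the two oriented edge responses, spatially
aligned via nearest-neighbour upsampling of the half-resolution colour image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._util import round_half_up

#: subband -> colour channel assignment, fixed by design
CHANNEL_ASSIGNMENT = {"R": "LL", "G": "LH", "B": "HL"}

ORIENTATION_CONVENTION = (
    "LH = vertical detail (row highpass, responds to horizontal edges); "
    "HL = horizontal detail (column highpass, responds to vertical edges)"
)


@dataclass
class Subbands:
    """Single-level Haar subbands of a grayscale region (coefficient units)."""

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray
    level: int = 1
    #: shape of the original region before odd-dimension edge padding
    orig_shape: tuple = None

    def __post_init__(self):
        shapes = {self.LL.shape, self.LH.shape, self.HL.shape, self.HH.shape}
        if len(shapes) != 1:
            raise ValueError(f"subbands must share one shape, got {shapes}")
        if self.orig_shape is None:
            self.orig_shape = (2 * self.LL.shape[0], 2 * self.LL.shape[1])


@dataclass
class FusionImage:
    """3-channel fusion image plus the 4-channel (gray + fusion) stack.

    ``channel_map`` records the subband->channel assignment and the per-band
    normalisation parameters, sufficient to re-derive ``rgb`` from the
    subbands bit-exactly.
    """

    rgb: np.ndarray
    four_channel: np.ndarray
    channel_map: dict = field(default_factory=dict)


def dwt2_haar(region) -> Subbands:
    """Single-level orthonormal 2-D Haar decomposition.

    Odd dimensions are handled by symmetric edge replication of one
    row/column before the blockwise transform.
    """
    x = np.asarray(region, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"region must be 2-D and at least 2x2, got shape {x.shape}")
    orig_shape = x.shape
    if x.shape[0] % 2:
        x = np.vstack([x, x[-1:, :]])
    if x.shape[1] % 2:
        x = np.hstack([x, x[:, -1:]])
    a = x[0::2, 0::2]
    b = x[0::2, 1::2]
    c = x[1::2, 0::2]
    d = x[1::2, 1::2]
    return Subbands(
        LL=(a + b + c + d) / 2.0,
        LH=((a + b) - (c + d)) / 2.0,
        HL=((a + c) - (b + d)) / 2.0,
        HH=(a - b - c + d) / 2.0,
        orig_shape=orig_shape,
    )


def idwt2_haar(sb: Subbands) -> np.ndarray:
    """Inverse of :func:`dwt2_haar`; exact up to floating-point roundoff."""
    LL, LH, HL, HH = sb.LL, sb.LH, sb.HL, sb.HH
    a = (LL + LH + HL + HH) / 2.0
    b = (LL + LH - HL - HH) / 2.0
    c = (LL - LH + HL - HH) / 2.0
    d = (LL - LH - HL + HH) / 2.0
    h, w = LL.shape
    out = np.empty((2 * h, 2 * w), dtype=float)
    out[0::2, 0::2] = a
    out[0::2, 1::2] = b
    out[1::2, 0::2] = c
    out[1::2, 1::2] = d
    r, c_ = sb.orig_shape
    return out[:r, :c_]


def _rescale_band(band: np.ndarray):
    """Min-max rescale one subband to uint8; constant bands map to 0."""
    mn = float(band.min())
    mx = float(band.max())
    if mx == mn:
        return np.zeros(band.shape, dtype=np.uint8), mn, mx
    scaled = (band - mn) / (mx - mn) * 255.0
    return round_half_up(scaled).astype(np.uint8), mn, mx


def subbands_to_rgb(sb: Subbands) -> FusionImage:
    """Map LL/LH/HL to R/G/B with independent per-band 8-bit rescaling.

    Rounding is half-up (a band value halfway between two intensity codes
    maps to the higher one).  The returned :class:`FusionImage` has its
    ``four_channel`` field unset (None); use :func:`fuse` for the full stack.
    """
    channels = []
    channel_map: dict[str, Any] = {
        "assignment": dict(CHANNEL_ASSIGNMENT),
        "orientation": ORIENTATION_CONVENTION,
        "normalization": {},
        "rounding": "half-up",
    }
    for chan, name in CHANNEL_ASSIGNMENT.items():
        band = getattr(sb, name)
        scaled, mn, mx = _rescale_band(band)
        channels.append(scaled)
        channel_map["normalization"][name] = {"min": mn, "max": mx}
    rgb = np.stack(channels, axis=-1)
    return FusionImage(rgb=rgb, four_channel=None, channel_map=channel_map)


def upsample_nearest(image: np.ndarray, target_shape) -> np.ndarray:
    """2x nearest-neighbour upsampling, cropped to ``target_shape``."""
    up = np.repeat(np.repeat(image, 2, axis=0), 2, axis=1)
    return up[: target_shape[0], : target_shape[1]]


def fuse(crop) -> FusionImage:
    """Build the full 4-channel representation of a grayscale crop.

    Channel order is fixed as [gray, R=LL, G=LH, B=HL] (channel-last array of
    shape ``(H, W, 4)``); the half-resolution colour image is upsampled by
    nearest neighbour so all four channels align spatially with the crop.
    """
    crop = np.asarray(crop)
    sb = dwt2_haar(crop)
    fi = subbands_to_rgb(sb)
    rgb_full = upsample_nearest(fi.rgb, crop.shape)
    four = np.concatenate([crop.astype(np.uint8)[..., None], rgb_full], axis=-1)
    fi.channel_map["upsampling"] = "nearest-neighbour x2, cropped to crop shape"
    fi.channel_map["four_channel_order"] = ["gray", "R=LL", "G=LH", "B=HL"]
    return FusionImage(rgb=fi.rgb, four_channel=four, channel_map=fi.channel_map)
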