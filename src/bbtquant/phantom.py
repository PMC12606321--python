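"""Synthetic radiograph phantoms with exactly known ground truth.

Clinical radiographs of benign bone lesions cannot be redistributed, so the
package ships a phantom generator that emulates the features the pipeline
depends on and records their exact ground truth:

* a bone-like background — mean level plus a vertically smoothed gradient and
  a smooth random field, so wavelet subbands are non-trivial — with additive
  Gaussian noise;
* a single bright lesion whose contour is an ellipse with a truncated random
  Fourier perturbation of the radius (smooth but irregular, the shape class
  for which pixel-count area beats a width x height product);
* a dark calibration strip at the left edge containing a solid vertical
  scale bar of known pixel height and a bitmap-font label such as "13 cm".

Everything is deterministic given the config seed.  The true mask, true
calibration and true measurement are returned alongside the image, so every
downstream stage (detection, segmentation, calibration, measurement,
longitudinal comparison) can be scored against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage

from . import _font
from .measure import Measurement, measure
from .scalebar import Calibration

_BAR_WIDTH_PX = 3  # rendered bar thickness
_LABEL_GAP_PX = 6  # gap between label baseline and bar top


class PhantomConfigError(ValueError):
    """Lesion or scale bar would not fit the configured image."""


@dataclass
class PhantomConfig:
    """Geometry, intensity and calibration parameters of one phantom.

    Defaults are desk-scale: a 512x512 image (full clinical resolution is a
    config away), a mid-gray bony background with moderate noise, a clearly
    visible lesion, and a 13 cm / 160 px scale bar.
    """

    image_size: tuple[int, int] = (512, 512)
    background_level: float = 90.0
    noise_sigma: float = 8.0
    lesion_center: tuple[float, float] = (256.0, 300.0)
    lesion_radii: tuple[float, float] = (50.0, 30.0)  # (row, col) semi-axes, px
    contour_wobble: float = 0.15  # relative radial perturbation amplitude
    wobble_harmonics: int = 4
    lesion_contrast: float = 45.0
    scale_bar_length_cm: float = 13.0
    scale_bar_height_px: int = 160
    scale_bar_col: int = 10  # bar's left column inside the strip
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        strip_w = int(np.floor(0.10 * w))
        if not (0.0 <= self.contour_wobble < 0.5):
            raise PhantomConfigError("contour_wobble must be in [0, 0.5)")
        if self.scale_bar_height_px < 20:
            raise PhantomConfigError("scale bar must be at least 20 px tall")
        if self.scale_bar_col < 0 or self.scale_bar_col + _BAR_WIDTH_PX > strip_w:
            raise PhantomConfigError(
                f"scale bar columns must lie within the leftmost 10% "
                f"({strip_w} columns for width {w})"
            )
        label_h = 7 * _font.GLYPH_SCALE
        if self.scale_bar_height_px + label_h + 2 * _LABEL_GAP_PX + 4 > h:
            raise PhantomConfigError("scale bar + label taller than the image")
        cr, cc = self.lesion_center
        rr, rc = self.lesion_radii
        max_rr = rr * (1.0 + self.contour_wobble) + 2
        max_rc = rc * (1.0 + self.contour_wobble) + 2
        if not (max_rr <= cr <= h - 1 - max_rr):
            raise PhantomConfigError("lesion exceeds image rows")
        if not (strip_w + max_rc <= cc <= w - 1 - max_rc):
            raise PhantomConfigError(
                "lesion must fit between the calibration strip and the right edge"
            )

    @property
    def scale_bar_label(self) -> str:
        v = self.scale_bar_length_cm
        text = f"{v:g}"
        return f"{text} cm"

    @property
    def true_mm_per_px(self) -> float:
        return self.scale_bar_length_cm * 10.0 / self.scale_bar_height_px


@dataclass
class PhantomSample:
    """One phantom image with its exact ground truth."""

    image: np.ndarray
    mask: np.ndarray
    true_calibration: Calibration
    true_measurement: Measurement
    config: PhantomConfig

    def truth_dict(self) -> dict:
        return {
            "calibration": self.true_calibration.to_dict(),
            "measurement": self.true_measurement.to_dict(),
            "config": _config_to_jsonable(self.config),
        }


def _config_to_jsonable(config: PhantomConfig) -> dict:
    d = asdict(config)
    for key in ("image_size", "lesion_center", "lesion_radii"):
        d[key] = list(d[key])
    return d


def config_from_jsonable(d: dict) -> PhantomConfig:
    d = dict(d)
    for key in ("image_size", "lesion_center", "lesion_radii"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomConfig(**d)


def _wobble_profile(theta: np.ndarray, harmonics: int, rng: np.random.Generator):
    """Random truncated Fourier series, normalised to peak amplitude 1."""
    coeffs_a = rng.standard_normal(harmonics)
    coeffs_b = rng.standard_normal(harmonics)
    pert = np.zeros_like(theta)
    for k in range(1, harmonics + 1):
        pert += coeffs_a[k - 1] * np.cos(k * theta) + coeffs_b[k - 1] * np.sin(k * theta)
    peak = np.abs(pert).max()
    if peak == 0:
        return np.zeros_like(theta)
    return pert / peak


def lesion_mask(
    shape,
    center,
    radii,
    wobble: float = 0.0,
    harmonics: int = 4,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Discrete Fourier-perturbed ellipse mask.

    A pixel is inside iff its normalised elliptical radius is at most
    ``1 + wobble * f(theta)`` where f is a random truncated Fourier series
    with unit peak amplitude.  ``wobble=0`` gives the plain discrete ellipse.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    u = (rows - center[0]) / radii[0]
    v = (cols - center[1]) / radii[1]
    rad = np.hypot(u, v)
    if wobble == 0.0:
        return rad <= 1.0
    theta = np.arctan2(u, v)
    rho = 1.0 + wobble * _wobble_profile(theta, harmonics, rng)
    return rad <= rho


def render_scale_bar(
    length_cm: float,
    height_px: int,
    strip_shape: tuple[int, int] | None = None,
    bar_col: int = 10,
    bar_top: int | None = None,
) -> tuple[np.ndarray, str]:
    """Render a calibration strip: one solid vertical bar plus its label.

    Returns ``(strip, label_text)``.  The bar is exactly ``height_px`` rows of
    intensity 255 and is the tallest connected component (glyphs are 14 px
    tall, below the 20 px minimum bar height); the label sits above the bar.
    """
    if height_px < 20:
        raise ValueError("height_px must be >= 20")
    label = f"{length_cm:g} cm"
    text_img = _font.render_text(label)
    label_h, label_w = text_img.shape
    min_h = height_px + label_h + 2 * _LABEL_GAP_PX
    if strip_shape is None:
        strip_shape = (min_h + 4, max(bar_col + _BAR_WIDTH_PX + 2, label_w + 4, 40))
    if label_w + 2 > strip_shape[1]:
        # narrow strip: drop the space between number and unit
        label = f"{length_cm:g}cm"
        text_img = _font.render_text(label)
        label_h, label_w = text_img.shape
        if label_w + 2 > strip_shape[1]:
            raise ValueError("strip too narrow for the scale label")
    strip = np.zeros(strip_shape, dtype=np.uint8)
    if bar_top is None:
        bar_top = (strip_shape[0] - height_px + label_h + _LABEL_GAP_PX) // 2
    if bar_top < label_h + _LABEL_GAP_PX or bar_top + height_px > strip_shape[0]:
        raise ValueError("bar + label do not fit the strip")
    strip[bar_top : bar_top + height_px, bar_col : bar_col + _BAR_WIDTH_PX] = 255
    text_r0 = bar_top - _LABEL_GAP_PX - label_h
    text_c0 = max(0, min(2, strip_shape[1] - label_w))
    sub = strip[text_r0 : text_r0 + label_h, text_c0 : text_c0 + label_w]
    np.maximum(sub, text_img[:, : sub.shape[1]], out=sub)
    return strip, label


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one phantom radiograph; deterministic given ``config.seed``."""
    config.validate()
    h, w = config.image_size
    rng = np.random.default_rng(config.seed)

    # draws happen in a fixed order so a series shares its lesion shape
    wobble_rng = np.random.default_rng(rng.integers(2**31))
    field_rng = np.random.default_rng(rng.integers(2**31))
    noise_rng = np.random.default_rng(rng.integers(2**31))

    # bone-like background: vertical gradient + smooth random field
    vert = np.linspace(-1.0, 1.0, h)[:, None]
    smooth = ndimage.gaussian_filter(
        field_rng.standard_normal((h, w)), sigma=min(h, w) / 8.0
    )
    smooth_amp = smooth.std() or 1.0
    img = config.background_level + 12.0 * vert + 10.0 * smooth / smooth_amp

    mask = lesion_mask(
        (h, w),
        config.lesion_center,
        config.lesion_radii,
        config.contour_wobble,
        config.wobble_harmonics,
        wobble_rng,
    )
    img = img + config.lesion_contrast * mask

    if config.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, config.noise_sigma, size=(h, w))

    # calibration strip: near-black background, bright bar + label
    strip_w = int(np.floor(0.10 * w))
    strip_noise = np.clip(
        noise_rng.normal(8.0, min(config.noise_sigma, 4.0), size=(h, strip_w)), 0, 20
    )
    strip, label = render_scale_bar(
        config.scale_bar_length_cm,
        config.scale_bar_height_px,
        strip_shape=(h, strip_w),
        bar_col=config.scale_bar_col,
    )
    img[:, :strip_w] = np.where(strip > 0, strip, strip_noise)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    calibration = Calibration(
        bar_height_px=config.scale_bar_height_px,
        bar_length_mm=config.scale_bar_length_cm * 10.0,
        ocr_text=label,
    )
    return PhantomSample(
        image=image,
        mask=mask,
        true_calibration=calibration,
        true_measurement=measure(mask, calibration),
        config=config,
    )


def generate_series(config: PhantomConfig, growth_factors) -> list[PhantomSample]:
    """Phantom series emulating follow-up visits of one lesion.

    Sample k has the lesion semi-axes scaled by ``sqrt(growth_factors[k])``,
    so true areas scale by the growth factors (within discretisation
    tolerance).  The lesion shape (wobble realisation) is shared across the
    series; it is the same lesion at different visits.
    """
    growth_factors = list(growth_factors)
    if any(g <= 0 for g in growth_factors):
        raise PhantomConfigError("growth factors must be positive")
    samples = []
    for g in growth_factors:
        s = np.sqrt(g)
        cfg = replace(
            config,
            lesion_radii=(config.lesion_radii[0] * s, config.lesion_radii[1] * s),
        )
        samples.append(generate_phantom(cfg))
    return samples
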