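"""Phantom generator: determinism, geometry ground truth, scale-bar rendering."""

import numpy as np
import pytest

from bbtquant.ocr import TemplateOcr
from bbtquant.phantom import (
    PhantomConfig,
    PhantomConfigError,
    generate_phantom,
    generate_series,
    render_scale_bar,
)
from bbtquant.scalebar import binarize, parse_scale_text, tallest_component


class TestGeneratePhantom:
    def test_bitwise_determinism(self):
        a = generate_phantom(PhantomConfig(seed=7))
        b = generate_phantom(PhantomConfig(seed=7))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_different_seeds_differ(self):
        a = generate_phantom(PhantomConfig(seed=1))
        b = generate_phantom(PhantomConfig(seed=2))
        assert not np.array_equal(a.image, b.image)

    def test_wobble_free_ellipse_pixel_count(self, ellipse_phantom):
        n = ellipse_phantom.mask.sum()
        assert n == pytest.approx(np.pi * 50 * 30, rel=0.02)
        assert ellipse_phantom.true_measurement.N_pixels == n

    def test_negative_control_records_mask_without_signal(self):
        cfg = PhantomConfig(noise_sigma=0.0, lesion_contrast=0.0)
        sample = generate_phantom(cfg)
        assert sample.mask.sum() > 0
        inside = sample.image[sample.mask].mean()
        ring = sample.image[~sample.mask & (np.arange(512)[:, None] > 100)].mean()
        assert abs(float(inside) - float(ring)) < 15.0  # no lesion contrast

    def test_bar_is_tallest_component(self, default_phantom):
        strip = default_phantom.image[:, :51]
        _, height = tallest_component(binarize(strip))
        assert height == default_phantom.config.scale_bar_height_px

    def test_truth_consistency(self, default_phantom):
        t = default_phantom.true_measurement
        assert t.N_pixels == default_phantom.mask.sum()
        assert t.area_mm2 == pytest.approx(
            t.N_pixels * default_phantom.true_calibration.mm_per_px**2
        )

    @pytest.mark.parametrize(
        "bad",
        [
            {"lesion_center": (10.0, 300.0)},        # lesion off the top
            {"lesion_center": (256.0, 30.0)},        # lesion inside the strip
            {"contour_wobble": 0.6},
            {"scale_bar_height_px": 10},
            {"scale_bar_col": 60},                   # outside the leftmost 10%
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(PhantomConfigError):
            generate_phantom(PhantomConfig(**bad))


class TestGenerateSeries:
    def test_constant_series_equal_areas(self):
        samples = generate_series(PhantomConfig(), [1.0, 1.0, 1.0])
        areas = [s.mask.sum() for s in samples]
        assert max(areas) / min(areas) == pytest.approx(1.0, rel=0.03)

    def test_growth_ratio_tracks_factor(self):
        samples = generate_series(PhantomConfig(), [1.0, 1.2])
        ratio = samples[1].mask.sum() / samples[0].mask.sum()
        assert 1.16 <= ratio <= 1.24

    def test_same_lesion_shape_across_series(self):
        """The wobble realisation is shared: same lesion, different visit."""
        a, b = generate_series(PhantomConfig(contour_wobble=0.2), [1.0, 1.0])
        assert np.array_equal(a.mask, b.mask)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(PhantomConfigError):
            generate_series(PhantomConfig(), [1.0, -0.5])

    def test_overgrown_lesion_rejected(self):
        cfg = PhantomConfig(lesion_radii=(120.0, 100.0), lesion_center=(256.0, 320.0))
        with pytest.raises(PhantomConfigError):
            generate_series(cfg, [1.0, 4.0])


class TestRenderScaleBar:
    def test_bar_height_423(self):
        strip, label = render_scale_bar(13, 423)
        _, height = tallest_component(binarize(strip))
        assert height == 423
        assert label == "13 cm"

    def test_fixture_ocr_roundtrip(self):
        strip, _ = render_scale_bar(10, 100)
        results = TemplateOcr().recognize(strip)
        assert len(results) == 1
        assert results[0].text == "10 cm"

    def test_parse_of_read_label_24cm(self):
        strip, _ = render_scale_bar(24, 451)
        text = TemplateOcr().recognize(strip)[0].text
        assert parse_scale_text(text) == 240.0

    def test_minimum_height_enforced(self):
        with pytest.raises(ValueError):
            render_scale_bar(13, 19)
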