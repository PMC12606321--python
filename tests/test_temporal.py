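"""Centroid alignment, area-change flagging and contour overlays."""

import numpy as np
import pytest

from bbtquant.measure import measure
from bbtquant.phantom import PhantomConfig, generate_series
from bbtquant.scalebar import Calibration
from bbtquant.temporal import (
    align,
    area_change,
    centroid,
    compare_series,
    overlay_contours,
)


def cal(mm_per_px=1.0):
    return Calibration(bar_height_px=100, bar_length_mm=100 * mm_per_px)


def meas_with_area(area):
    """Measurement stub with a given mm^2 area (square mask)."""
    side = int(round(np.sqrt(area)))
    m = np.zeros((side + 4, side + 4), dtype=bool)
    m[2 : 2 + side, 2 : 2 + side] = True
    return measure(m, cal(np.sqrt(area) / side))


class TestCentroid:
    def test_block(self):
        m = np.zeros((30, 30), dtype=bool)
        m[10:12, 20:22] = True
        assert centroid(m) == (10.5, 20.5)

    def test_single_pixel(self):
        m = np.zeros((10, 10), dtype=bool)
        m[5, 7] = True
        assert centroid(m) == (5.0, 7.0)

    def test_l_tromino(self):
        m = np.zeros((4, 4), dtype=bool)
        m[0, 0] = m[1, 0] = m[1, 1] = True
        r, c = centroid(m)
        assert r == pytest.approx(2 / 3)
        assert c == pytest.approx(1 / 3)

    def test_empty(self):
        with pytest.raises(ValueError):
            centroid(np.zeros((3, 3), dtype=bool))


class TestAlign:
    @staticmethod
    def blob(offset, shape=(64, 64)):
        m = np.zeros(shape, dtype=bool)
        r, c = offset
        m[r : r + 5, c : c + 7] = True
        return m

    def test_identical_masks_align_identically(self):
        out = align([self.blob((5, 5)), self.blob((40, 30)), self.blob((20, 50))])
        assert np.array_equal(out[0], out[1])
        assert np.array_equal(out[1], out[2])

    def test_centroids_at_canvas_center(self):
        out = align([self.blob((5, 5)), self.blob((40, 30))])
        H, W = out[0].shape
        for m in out:
            r, c = centroid(m)
            assert abs(r - H // 2) <= 0.5 and abs(c - W // 2) <= 0.5

    def test_translation_invariance(self):
        base = [self.blob((10, 10)), self.blob((30, 30))]
        shifted = [self.blob((13, 17)), self.blob((30, 30))]
        a, b = align(base), align(shifted)
        assert np.array_equal(a[0], b[0])

    def test_areas_preserved(self):
        masks = [self.blob((5, 5)), self.blob((40, 30))]
        out = align(masks)
        assert [m.sum() for m in out] == [m.sum() for m in masks]

    def test_needs_two(self):
        with pytest.raises(ValueError):
            align([self.blob((5, 5))])


class TestAreaChange:
    def test_growth_flagged(self):
        changes = area_change([meas_with_area(100.0), meas_with_area(112.0)], 10.0)
        assert changes[0].pct_change == pytest.approx(12.0, abs=0.01)
        assert changes[0].flagged

    def test_small_change_not_flagged(self):
        changes = area_change([meas_with_area(100.0), meas_with_area(105.0)], 10.0)
        assert changes[0].pct_change == pytest.approx(5.0, abs=0.01)
        assert not changes[0].flagged

    def test_decrease_also_flagged(self):
        changes = area_change(
            [meas_with_area(100.0), meas_with_area(100.0), meas_with_area(89.0)], 10.0
        )
        consec = [c for c in changes if c.kind == "consecutive"]
        assert consec[1].pct_change == pytest.approx(-11.0, abs=0.01)
        assert consec[1].flagged
        assert not consec[0].flagged

    def test_baseline_changes_reported(self):
        changes = area_change(
            [meas_with_area(100.0), meas_with_area(105.0), meas_with_area(112.0)], 10.0
        )
        baseline = [c for c in changes if c.kind == "baseline"]
        assert len(baseline) == 1
        assert baseline[0].pct_change == pytest.approx(12.0, abs=0.01)
        assert baseline[0].flagged

    def test_reversal_flips_sign_keeps_flags(self):
        ms = [meas_with_area(a) for a in (100.0, 120.0)]
        fwd = area_change(ms, 10.0)
        rev = area_change(ms[::-1], 10.0)
        assert fwd[0].flagged == rev[0].flagged
        # 100 -> 120 is +20%; 120 -> 100 is -16.7%: signs oppose
        assert np.sign(fwd[0].pct_change) == -np.sign(rev[0].pct_change)


class TestOverlay:
    def test_single_mask_contour(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        out = overlay_contours([m], colors=((255, 0, 0),))
        assert tuple(out[5, 5]) == (255, 0, 0)
        assert tuple(out[10, 10]) == (0, 0, 0)  # interior unpainted

    def test_coincident_contours_blend(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        out = overlay_contours([m, m])
        assert tuple(out[5, 5]) == (255, 255, 0)  # red + green

    def test_palette_cycles_with_warning(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2:6, 2:6] = True
        with pytest.warns(UserWarning):
            overlay_contours([m] * 4)


class TestEndToEndSeries:
    def test_phantom_series_flags_growth_not_control(self):
        cfg = PhantomConfig()
        grown = generate_series(cfg, [1.0, 1.15])
        control = generate_series(cfg, [1.0, 1.05])
        grown_cmp = compare_series(
            [s.mask for s in grown], [s.true_calibration for s in grown], 10.0
        )
        control_cmp = compare_series(
            [s.mask for s in control], [s.true_calibration for s in control], 10.0
        )
        assert grown_cmp.any_flagged
        assert not control_cmp.any_flagged

    def test_growth_overlay_outer_contour_is_later_timepoint(self):
        samples = generate_series(PhantomConfig(contour_wobble=0.0), [1.0, 1.2])
        aligned = align([s.mask for s in samples])
        # along the horizontal centreline the later (green) contour lies outside
        H, W = aligned[0].shape
        row = H // 2
        first_cols = np.nonzero(aligned[0][row])[0]
        second_cols = np.nonzero(aligned[1][row])[0]
        assert second_cols.min() <= first_cols.min()
        assert second_cols.max() >= first_cols.max()
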