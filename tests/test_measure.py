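"""Millimetre size/area computation and the deviation report."""

import numpy as np
import pandas as pd
import pytest

from bbtquant.datasets import reference_measurements
from bbtquant.measure import (
    area_mm2,
    deviation_report,
    measure,
    min_bounding_box,
    size_mm,
)
from bbtquant.scalebar import Calibration
from oracles import area_oracle


def cal(mm_per_px: float) -> Calibration:
    return Calibration(bar_height_px=1000, bar_length_mm=1000 * mm_per_px)


class TestMinBoundingBox:
    def test_single_pixel(self):
        m = np.zeros((6, 6), dtype=bool)
        m[3, 2] = True
        box = min_bounding_box(m)
        assert (box.width, box.height) == (1, 1)

    def test_two_corners(self):
        m = np.zeros((10, 12), dtype=bool)
        m[0, 0] = m[4, 9] = True
        box = min_bounding_box(m)
        assert (box.width, box.height) == (10, 5)

    def test_ellipse_extents(self, ellipse_phantom):
        mask = ellipse_phantom.mask
        box = min_bounding_box(mask)
        rows, cols = np.nonzero(mask)
        assert box.as_tuple() == (rows.min(), cols.min(), rows.max() + 1, cols.max() + 1)

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            min_bounding_box(np.zeros((4, 4), dtype=bool))


class TestSizeAndArea:
    def test_size_products(self):
        m = np.zeros((200, 200), dtype=bool)
        m[10:110, 20:120] = True  # 100 x 100 px
        w, h = size_mm(min_bounding_box(m), cal(0.5))
        assert (w, h) == (50.0, 50.0)
        w, h = size_mm(min_bounding_box(m), cal(1.0))
        assert (w, h) == (100.0, 100.0)

    def test_area_simple(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5:25, 5:25] = True  # 400 px
        assert area_mm2(m, cal(0.5)) == pytest.approx(100.0)

    def test_checkerboard_below_box_area(self):
        m = np.indices((8, 8)).sum(axis=0) % 2 == 0
        meas = measure(m, cal(0.5))
        assert meas.area_mm2 < meas.width_mm * meas.height_mm

    def test_scaling_law_exact(self, rng):
        m = rng.random((32, 32)) < 0.4
        m[3, 3] = True
        base = measure(m, cal(0.25))
        scaled = measure(m, cal(0.25 * 3.0))
        assert scaled.width_mm == pytest.approx(3.0 * base.width_mm, abs=0)
        assert scaled.height_mm == pytest.approx(3.0 * base.height_mm, abs=0)
        assert scaled.area_mm2 == pytest.approx(9.0 * base.area_mm2, rel=1e-15)

    def test_area_matches_per_pixel_oracle(self, rng):
        for _ in range(5):
            m = rng.random((12, 15)) < 0.5
            if not m.any():
                continue
            assert area_mm2(m, cal(0.37)) == pytest.approx(area_oracle(m, 0.37))

    def test_phantom_ellipse_area_within_3pct(self, ellipse_phantom):
        meas = measure(ellipse_phantom.mask, cal(0.5))
        analytic = np.pi * (50 * 0.5) * (30 * 0.5)
        assert meas.area_mm2 == pytest.approx(analytic, rel=0.03)

    def test_empty_mask_zero_area_with_warning(self):
        with pytest.warns(UserWarning):
            assert area_mm2(np.zeros((4, 4), dtype=bool), cal(1.0)) == 0.0


class TestDeviationReport:
    def test_identical_tables_all_zero(self):
        df = pd.DataFrame({"width_mm": [10.0, 20.0], "height_mm": [5.0, 8.0]})
        rep = deviation_report(df, df)
        assert rep.mean_pct_width == rep.mean_pct_height == rep.max_pct == 0.0

    def test_reference_case_deviations(self):
        pred, gt = reference_measurements()
        rep = deviation_report(pred, gt)
        assert rep.per_case.abs_dev_width_mm.iloc[0] == 0.19
        assert rep.per_case.abs_dev_height_mm.iloc[2] == 0.20

    def test_reference_aggregates(self):
        pred, gt = reference_measurements()
        rep = deviation_report(pred, gt)
        assert rep.mean_pct_width == 0.58
        assert rep.mean_pct_height == 0.38
        assert rep.max_pct == 1.06
        assert (rep.max_case, rep.max_axis) == (1, "width")

    def test_errors(self):
        a = pd.DataFrame({"width_mm": [1.0], "height_mm": [1.0]})
        b = pd.DataFrame({"width_mm": [1.0, 2.0], "height_mm": [1.0, 2.0]})
        with pytest.raises(ValueError):
            deviation_report(a, b)
        with pytest.raises(ValueError):
            deviation_report(a, pd.DataFrame({"width_mm": [0.0], "height_mm": [1.0]}))
        with pytest.raises(ValueError):
            deviation_report(a, pd.DataFrame({"width_mm": [1.0]}))
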