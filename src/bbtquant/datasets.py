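"""Small bundled reference tables used by the validation workflow.

The measurement validation table below lists ten representative benign bone
tumour cases with the pipeline-predicted and expert (radiologist) bounding-box
sizes in millimetres, plus the pipeline's pixel-count area.  Feeding the
predicted/ground-truth columns through :func:`bbtquant.measure.deviation_report`
reproduces the published per-case deviations and their aggregates (mean width
deviation 0.58%, mean height deviation 0.38%, maximum 1.06%).
"""

from __future__ import annotations

import pandas as pd

# columns: pred width_mm, pred height_mm, pred area_mm2, gt width_mm, gt height_mm
_REFERENCE_ROWS = [
    (17.70, 33.50, 416.0, 17.89, 33.58),
    (13.30, 33.00, 335.3, 13.40, 32.92),
    (10.00, 20.60, 115.2, 10.09, 20.40),
    (7.04, 18.96, 66.38, 7.01, 18.88),
    (6.12, 12.85, 54.97, 6.08, 12.81),
    (24.78, 41.91, 739.81, 24.76, 41.98),
    (7.34, 13.46, 71.3, 7.41, 13.55),
    (11.62, 20.49, 130.24, 11.68, 20.61),
    (5.51, 15.60, 47.3, 5.51, 15.58),
    (11.62, 16.21, 135.39, 11.57, 16.20),
]

# scale-bar worked examples: (bar height px, label, printed two-decimal px/mm)
REFERENCE_CALIBRATIONS = [
    {"bar_height_px": 423, "label": "13 cm", "printed_ratio": 3.25},
    {"bar_height_px": 431, "label": "13 cm", "printed_ratio": 3.31},
]


def reference_measurements() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (predicted, ground_truth) tables of the ten validation cases.

    Both frames carry ``width_mm`` and ``height_mm``; the predicted frame
    additionally carries the pixel-count ``area_mm2``.
    """
    pred = pd.DataFrame(
        [(w, h, a) for w, h, a, _, _ in _REFERENCE_ROWS],
        columns=["width_mm", "height_mm", "area_mm2"],
    )
    gt = pd.DataFrame(
        [(gw, gh) for _, _, _, gw, gh in _REFERENCE_ROWS],
        columns=["width_mm", "height_mm"],
    )
    return pred, gt
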