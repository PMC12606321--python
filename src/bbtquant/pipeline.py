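"""End-to-end composition: detect -> fuse -> segment -> calibrate -> measure -> compare.

``run_pipeline`` processes one or more radiographs of the same lesion in
temporal order.  Each stage's output is persisted (det.json, fused.npz,
mask.png, calib.json, meas.json and, for series, report.json) and every
threshold used is recorded in the report for auditability.

Segmentation backend: if a trained U-Net model file is supplied it is
applied to the padded crop; otherwise a classical fallback (Otsu threshold
of the background-flattened crop, largest component) is used so the pipeline
runs without any training step.  Calibration failure does not abort the run:
the report degrades to pixel units with an explicit warning and a distinct
status.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import filters, measure as skmeasure
from skimage.transform import resize

from . import io as bio
from .config import PipelineConfig
from .detection import BoundingBox, detect_reference, pad_box
from .fusion import fuse
from .measure import Measurement, measure, min_bounding_box
from .scalebar import Calibration, CalibrationError, calibrate
from .temporal import SeriesComparison, compare_series

logger = logging.getLogger("bbtquant")

#: run_pipeline status codes (also used as CLI exit codes)
STATUS_OK = 0
STATUS_NO_CALIBRATION = 3  # measurements reported in pixel units


@dataclass
class PipelineResult:
    measurements: list[Measurement]
    calibrations: list[Calibration | None]
    masks: list[np.ndarray]
    series: SeriesComparison | None
    status: int
    warnings: list[str] = field(default_factory=list)


def segment_classical(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Threshold-based fallback segmenter inside a padded crop.

    Background-flattened Otsu threshold, then the largest connected
    component, returned as a full-image boolean mask.
    """
    crop = np.asarray(image, dtype=float)[box.row0 : box.row1, box.col0 : box.col1]
    background = ndimage.gaussian_filter(crop, sigma=max(crop.shape) / 2.0)
    residual = ndimage.gaussian_filter(crop - background, sigma=1.5)
    thr = filters.threshold_otsu(residual)
    fg = residual > thr
    labels = skmeasure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise RuntimeError("segmentation found no foreground in the crop")
    props = skmeasure.regionprops(labels)
    best = max(props, key=lambda p: p.area)
    full = np.zeros(image.shape, dtype=bool)
    full[box.row0 : box.row1, box.col0 : box.col1] = labels == best.label
    return full


def segment_with_model(image: np.ndarray, box: BoundingBox, model, config: PipelineConfig):
    """Apply a trained U-Net to the padded crop and paste the mask back."""
    from .segmentation.train import patch_channels

    crop = np.asarray(image)[box.row0 : box.row1, box.col0 : box.col1]
    patch = resize(crop.astype(float), (64, 64), order=1, preserve_range=True)
    patch = np.clip(np.rint(patch), 0, 255).astype(np.uint8)
    x = patch_channels(patch, config.channels_mode)[None]
    pred = model.predict(x)[0].astype(float)
    back = resize(pred, crop.shape, order=0, preserve_range=True) > 0.5
    full = np.zeros(image.shape, dtype=bool)
    full[box.row0 : box.row1, box.col0 : box.col1] = back
    return full


def run_pipeline(
    image_paths,
    config: PipelineConfig | None = None,
    out_dir=None,
    model=None,
) -> PipelineResult:
    """Process ordered radiographs of one lesion; compare across timepoints.

    Raises ``RuntimeError`` naming the failing stage for unrecoverable
    failures (no detection, empty segmentation); calibration failures
    degrade to pixel-unit reporting with ``STATUS_NO_CALIBRATION``.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    masks, calibrations, measurements, warnings_ = [], [], [], []
    status = STATUS_OK
    for k, path in enumerate(image_paths):
        image = bio.read_image(path)

        detections = detect_reference(image, exclude_left_fraction=config.roi_fraction)
        if not detections:
            raise RuntimeError(f"stage detect: no lesion found in {path}")
        det = detections[0]
        box = pad_box(det.box, config.padding_px, image.shape)

        fused = fuse(image[box.row0 : box.row1, box.col0 : box.col1])

        if model is not None:
            mask = segment_with_model(image, box, model, config)
        else:
            mask = segment_classical(image, box)
        if not mask.any():
            raise RuntimeError(f"stage segment: empty mask for {path}")

        calib: Calibration | None
        try:
            calib = calibrate(
                image,
                ocr_backend=config.make_ocr_backend(),
                roi_fraction=config.roi_fraction,
                threshold=config.binarize_threshold,
                rounding=config.rounding_mode,
            )
        except CalibrationError as exc:
            calib = None
            status = STATUS_NO_CALIBRATION
            msg = f"{path}: calibration failed ({exc}); reporting pixel units"
            warnings_.append(msg)
            logger.warning(msg)

        if calib is not None:
            meas = measure(mask, calib)
        else:
            box_t = min_bounding_box(mask)
            meas = Measurement(
                W_pixels=box_t.width,
                H_pixels=box_t.height,
                width_mm=float("nan"),
                height_mm=float("nan"),
                N_pixels=int(mask.sum()),
                area_mm2=float("nan"),
                calibration=None,
            )
        masks.append(mask)
        calibrations.append(calib)
        measurements.append(meas)

        if out_dir is not None:
            stem = f"t{k}"
            bio.write_json(
                out_dir / f"{stem}_det.json",
                {"box": det.box.as_tuple(), "score": det.score, "padded": box.as_tuple()},
            )
            np.savez(
                out_dir / f"{stem}_fused.npz",
                four_channel=fused.four_channel,
                channel_map=np.array(str(fused.channel_map)),
            )
            bio.write_mask(out_dir / f"{stem}_mask.png", mask)
            if calib is not None:
                bio.write_json(out_dir / f"{stem}_calib.json", calib.to_dict())
            bio.write_json(out_dir / f"{stem}_meas.json", meas.to_dict())

    series = None
    if len(image_paths) >= 2 and all(c is not None for c in calibrations):
        series = compare_series(masks, calibrations, config.area_change_pct)
        if out_dir is not None:
            bio.write_json(
                out_dir / "report.json",
                {
                    "config": asdict(config),
                    "measurements": [m.to_dict() for m in series.measurements],
                    "centroids": series.centroids,
                    "changes": [asdict(c) for c in series.changes],
                    "any_flagged": series.any_flagged,
                    "warnings": warnings_,
                },
            )
            bio.write_image(out_dir / "overlay.png", series.overlay)
    return PipelineResult(
        measurements=measurements,
        calibrations=calibrations,
        masks=masks,
        series=series,
        status=status,
        warnings=warnings_,
    )
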