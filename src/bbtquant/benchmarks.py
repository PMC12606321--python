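"""Phantom benchmarks exercising each pipeline stage against ground truth.

Each benchmark generates seeded phantom populations with randomised lesion
geometry, contrast and calibration, runs one pipeline stage, and scores it
against the recorded ground truth.  These are the quantitative claims the
package makes about itself; they are computed fresh on every run (see
``scripts/acceptance.py``) rather than stored.

Problem sizes follow the package's validation protocol: 100 phantoms for
detection, 50 for calibration round-trip and measurement recovery, 20 seeded
series for temporal flagging, and a 200-train / 50-test split (up to 30
epochs, 64 px patches) for the segmentation arm.
"""

from __future__ import annotations

import numpy as np

from .detection import detect_reference, map_at_50, mask_bounding_box
from .measure import measure
from .phantom import PhantomConfig, generate_phantom, generate_series
from .scalebar import calibrate
from .segmentation import TrainConfig, evaluate_model, make_patch_dataset, train
from .segmentation.unet import build_model
from .temporal import area_change


def random_config(rng: np.random.Generator, image_size=(512, 512)) -> PhantomConfig:
    """Draw a randomised but always-valid phantom configuration."""
    h, w = image_size
    strip_w = int(np.floor(0.10 * w))
    r_row = float(rng.uniform(30, 60))
    r_col = float(rng.uniform(20, 45))
    wobble = float(rng.uniform(0.05, 0.25))
    margin_r = r_row * (1 + wobble) + 4
    margin_c = r_col * (1 + wobble) + 4
    center = (
        float(rng.uniform(margin_r, h - 1 - margin_r)),
        float(rng.uniform(strip_w + margin_c, w - 1 - margin_c)),
    )
    return PhantomConfig(
        image_size=image_size,
        background_level=float(rng.uniform(80, 110)),
        noise_sigma=float(rng.uniform(6, 10)),
        lesion_center=center,
        lesion_radii=(r_row, r_col),
        contour_wobble=wobble,
        wobble_harmonics=int(rng.integers(3, 7)),
        lesion_contrast=float(rng.uniform(38, 55)),
        scale_bar_length_cm=float(rng.choice([10, 13, 24])),
        scale_bar_height_px=int(rng.integers(120, 440)),
        scale_bar_col=int(rng.integers(4, strip_w - 4)),
        seed=int(rng.integers(2**31)),
    )


def detection_benchmark(seed: int = 0, n: int = 100) -> float:
    """mAP@0.5 of the reference detector over ``n`` random phantoms."""
    rng = np.random.default_rng(seed)
    detections, ground_truth = [], []
    for _ in range(n):
        sample = generate_phantom(random_config(rng))
        detections.append(detect_reference(sample.image))
        ground_truth.append([mask_bounding_box(sample.mask)])
    return map_at_50(detections, ground_truth)


def calibration_roundtrip_benchmark(seed: int = 0, n: int = 50) -> dict:
    """Scale-bar and measurement recovery over ``n`` random phantoms.

    Returns exact-recovery rates for bar height and label length (fixture
    OCR), and the rate at which measured width/height from the true mask and
    the detected calibration fall within one pixel-equivalent (1 px * S) of
    the recorded ground truth.
    """
    rng = np.random.default_rng(seed)
    height_ok = length_ok = extent_ok = 0
    for _ in range(n):
        sample = generate_phantom(random_config(rng))
        calib = calibrate(sample.image)
        if calib.bar_height_px == sample.config.scale_bar_height_px:
            height_ok += 1
        if calib.bar_length_mm == sample.config.scale_bar_length_cm * 10.0:
            length_ok += 1
        meas = measure(sample.mask, calib)
        truth = sample.true_measurement
        tol = calib.mm_per_px  # 1 px in mm
        if (
            abs(meas.width_mm - truth.width_mm) <= tol
            and abs(meas.height_mm - truth.height_mm) <= tol
        ):
            extent_ok += 1
    return {
        "bar_height_recovery_rate": height_ok / n,
        "bar_length_recovery_rate": length_ok / n,
        "extent_within_1px_rate": extent_ok / n,
        "n": n,
    }


def temporal_benchmark(seed: int = 0, n_seeds: int = 20, threshold_pct: float = 10.0) -> dict:
    """Flagging accuracy on growth vs stable phantom series.

    For each of ``n_seeds`` random lesions, a 15% true-area growth series
    must be flagged and a 5% series must not be.  Areas are measured from
    the true masks and per-visit calibrations, i.e. the criterion sees the
    same mm^2 quantities the clinical report would.
    """
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    growth_correct = stable_correct = 0
    for _ in range(n_seeds):
        cfg = random_config(rng)
        # leave headroom so the grown lesion still fits the image
        cfg = replace(
            cfg,
            lesion_radii=(cfg.lesion_radii[0] * 0.88, cfg.lesion_radii[1] * 0.88),
        )
        grown = generate_series(cfg, [1.0, 1.15])
        stable = generate_series(cfg, [1.0, 1.05])
        for series, expect_flag in ((grown, True), (stable, False)):
            meas = [s.true_measurement for s in series]
            changes = area_change(meas, threshold_pct)
            flagged = any(c.flagged for c in changes)
            if flagged == expect_flag:
                if expect_flag:
                    growth_correct += 1
                else:
                    stable_correct += 1
    return {
        "growth_flagged_rate": growth_correct / n_seeds,
        "stable_unflagged_rate": stable_correct / n_seeds,
        "n_seeds": n_seeds,
    }


def make_segmentation_split(seed: int = 0, n_train: int = 200, n_test: int = 50):
    """Disjoint random phantom populations for the segmentation benchmark."""
    rng = np.random.default_rng(seed)
    train_samples = [generate_phantom(random_config(rng)) for _ in range(n_train)]
    test_samples = [generate_phantom(random_config(rng)) for _ in range(n_test)]
    return train_samples, test_samples


def segmentation_benchmark(
    seed: int = 0,
    n_train: int = 200,
    n_test: int = 50,
    epochs: int = 30,
    channels_mode: str = "raw_plus_fusion",
) -> dict:
    """Train one U-Net arm on phantoms and score it on held-out phantoms."""
    train_samples, test_samples = make_segmentation_split(seed, n_train, n_test)
    config = TrainConfig(channels_mode=channels_mode, epochs=epochs, seed=seed)
    x_tr, y_tr = make_patch_dataset(train_samples, channels_mode, config.patch_size, config.padding_px)
    x_te, y_te = make_patch_dataset(test_samples, channels_mode, config.patch_size, config.padding_px)
    model = build_model(config.channels, config.base_width, config.seed)
    history = train(model, x_tr, y_tr, config)
    scores = evaluate_model(model, x_te, y_te)
    scores["epochs_run"] = len(history.train_loss)
    scores["n_train"] = n_train
    scores["n_test"] = n_test
    return scores
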