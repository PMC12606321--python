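"""Channel-ablation harness: raw vs fusion vs raw+fusion inputs.

Trains the same compact U-Net under the three input configurations on
identical train/test splits and seeds, and reports mean +/- sd of the three
segmentation metrics (mean accuracy, mean IoU, BF1) over the seeds.  The
point of the harness is the controlled comparison, not absolute numbers:
every arm sees exactly the same patches, protocol and initial-seed list.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .metrics import seg_metrics
from .train import TrainConfig, make_patch_dataset, train
from .unet import build_model

MODES = ("raw", "fusion", "raw_plus_fusion")


def evaluate_model(model, x_test, y_test, theta=None, batch_size: int = 8):
    """Per-sample metrics of a trained model on a test set, averaged."""
    rows = []
    for i in range(0, len(x_test), batch_size):
        pred = model.predict(x_test[i : i + batch_size])
        for p, g in zip(pred, y_test[i : i + batch_size]):
            m = seg_metrics(p.astype(bool), g.astype(bool), theta)
            rows.append(m.as_tuple())
    arr = np.array(rows)
    return {
        "mean_acc": float(arr[:, 0].mean()),
        "mean_iou": float(arr[:, 1].mean()),
        "bf1": float(arr[:, 2].mean()),
    }


def run_mode(train_samples, test_samples, config: TrainConfig):
    """Train one arm and score it on the held-out phantoms."""
    x_tr, y_tr = make_patch_dataset(
        train_samples, config.channels_mode, config.patch_size, config.padding_px
    )
    x_te, y_te = make_patch_dataset(
        test_samples, config.channels_mode, config.patch_size, config.padding_px
    )
    model = build_model(config.channels, config.base_width, config.seed)
    history = train(model, x_tr, y_tr, config)
    scores = evaluate_model(model, x_te, y_te)
    return model, history, scores


def ablation(train_samples, test_samples, seeds, config: TrainConfig | None = None) -> pd.DataFrame:
    """3 modes x 3 metrics table, mean +/- sd over ``seeds``.

    Returns a DataFrame indexed by mode with columns
    ``{metric}_mean`` and ``{metric}_sd`` for the three metrics.
    """
    if config is None:
        config = TrainConfig()
    records = []
    for mode in MODES:
        per_seed = []
        for seed in seeds:
            cfg = replace(config, channels_mode=mode, seed=seed)
            _, _, scores = run_mode(train_samples, test_samples, cfg)
            per_seed.append(scores)
        rec = {"mode": mode}
        for key in ("mean_acc", "mean_iou", "bf1"):
            vals = np.array([s[key] for s in per_seed])
            rec[f"{key}_mean"] = float(vals.mean())
            rec[f"{key}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        records.append(rec)
    return pd.DataFrame(records).set_index("mode")
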