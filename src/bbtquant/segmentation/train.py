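"""Training protocol and patch-dataset preparation for the segmentation net.

The training recipe is fixed by :class:`TrainConfig`: Adam with initial
learning rate 1e-3, piecewise-constant schedule multiplying the rate by 0.3
every 10 epochs, up to 50 epochs at mini-batch size 8, pixelwise two-class
cross-entropy, and early stopping after 4 consecutive validation checks
(one per epoch) without improvement of the validation loss.

Patches are built from phantom samples by cropping the padded lesion
bounding box (ground-truth box + fixed padding, default 25 px) and resizing
to a square patch; the input channels are selected by ``channels_mode``:

* ``raw``             — the grayscale crop (1 channel)
* ``fusion``          — the wavelet fusion image, LL/LH/HL as R/G/B (3)
* ``raw_plus_fusion`` — grayscale stacked with the fusion image (4)

Intensities are scaled to [0, 1] float32; masks are resampled with
nearest-neighbour so they stay strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from ..detection import pad_box
from ..fusion import fuse
from ..measure import min_bounding_box
from .unet import UNet, build_model

CHANNELS_BY_MODE = {"raw": 1, "fusion": 3, "raw_plus_fusion": 4}


@dataclass
class TrainConfig:
    channels_mode: str = "raw_plus_fusion"
    learning_rate: float = 1e-3
    schedule_factor: float = 0.3
    schedule_period: int = 10  # epochs between learning-rate drops
    epochs: int = 50
    batch_size: int = 8
    patience: int = 4  # validation checks without improvement before stop
    seed: int = 0
    patch_size: int = 64
    padding_px: int = 25
    base_width: int = 8
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.channels_mode not in CHANNELS_BY_MODE:
            raise ValueError(f"unknown channels_mode {self.channels_mode!r}")

    @property
    def channels(self) -> int:
        return CHANNELS_BY_MODE[self.channels_mode]

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate in force during ``epoch`` (0-based)."""
        return self.learning_rate * self.schedule_factor ** (epoch // self.schedule_period)


@dataclass
class History:
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    stopped_epoch: int | None = None


def crop_to_patch(image, mask, patch_size: int = 64, padding_px: int = 25):
    """Padded ground-truth-box crop of (image, mask), resized to a square patch."""
    box = pad_box(min_bounding_box(mask), padding_px, image.shape)
    img_crop = np.asarray(image)[box.row0 : box.row1, box.col0 : box.col1]
    mask_crop = np.asarray(mask)[box.row0 : box.row1, box.col0 : box.col1]
    img_p = resize(
        img_crop.astype(float), (patch_size, patch_size), order=1, preserve_range=True
    )
    mask_p = resize(
        mask_crop.astype(float), (patch_size, patch_size), order=0, preserve_range=True
    )
    return np.clip(np.rint(img_p), 0, 255).astype(np.uint8), mask_p > 0.5


def patch_channels(img_patch: np.ndarray, channels_mode: str) -> np.ndarray:
    """Channel-first float32 input in [0, 1] for one grayscale patch."""
    if channels_mode == "raw":
        stack = img_patch[None]
    else:
        four = fuse(img_patch).four_channel  # (H, W, 4): gray, R, G, B
        if channels_mode == "fusion":
            stack = four[..., 1:].transpose(2, 0, 1)
        else:
            stack = four.transpose(2, 0, 1)
    return (stack.astype(np.float32)) / 255.0


def make_patch_dataset(samples, channels_mode: str, patch_size: int = 64, padding_px: int = 25):
    """(X, Y) arrays from phantom samples: X (N,C,P,P) float32, Y (N,P,P) int."""
    xs, ys = [], []
    for s in samples:
        img_p, mask_p = crop_to_patch(s.image, s.mask, patch_size, padding_px)
        xs.append(patch_channels(img_p, channels_mode))
        ys.append(mask_p.astype(np.int64))
    return np.stack(xs), np.stack(ys)


def train(
    model: UNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> History:
    """Train in place per the fixed protocol; returns the epoch history.

    When no validation split is passed, the last ``val_fraction`` of the
    training set (after a seeded shuffle) is held out for the early-stopping
    checks.
    """
    if len(x_train) == 0:
        raise ValueError("empty training set")
    if not np.isin(np.unique(y_train), (0, 1)).all():
        raise ValueError("training masks must be binary")
    rng = np.random.default_rng(config.seed)
    if x_val is None:
        order = rng.permutation(len(x_train))
        n_val = max(1, int(round(config.val_fraction * len(x_train))))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        x_val, y_val = x_train[val_idx], y_train[val_idx]
        x_train, y_train = x_train[tr_idx], y_train[tr_idx]

    opt = model.make_optimizer(config.learning_rate)
    history = History()
    best_val = np.inf
    stale = 0
    for epoch in range(config.epochs):
        lr = config.lr_at_epoch(epoch)
        opt.lr = lr
        order = rng.permutation(len(x_train))
        losses, accs = [], []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            loss, grads, acc = model.loss_and_grads(x_train[idx], y_train[idx])
            opt.step(grads)
            losses.append(loss)
            accs.append(acc)
        val_loss, val_acc = model.evaluate(x_val, y_val, config.batch_size)
        history.train_loss.append(float(np.mean(losses)))
        history.train_acc.append(float(np.mean(accs)))
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        history.lr.append(lr)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                history.stopped_epoch = epoch
                break
    return history


def train_on_samples(samples, config: TrainConfig):
    """Convenience wrapper: patches -> model -> train.  Returns (model, history)."""
    if len(samples) < 20:
        raise ValueError("need at least 20 training samples")
    x, y = make_patch_dataset(samples, config.channels_mode, config.patch_size, config.padding_px)
    model = build_model(config.channels, config.base_width, config.seed)
    history = train(model, x, y, config)
    return model, history
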