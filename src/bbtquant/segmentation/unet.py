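"""Compact two-level U-Net for lesion-crop segmentation on CPU.

Encoder-decoder with skip connections, sized for 64-128 px crops:

    enc1: conv3x3 (C_in -> w)        64x64
    enc2: conv3x3 (w -> 2w)          32x32   (after 2x2 max pool)
    bott: conv3x3 (2w -> 4w)         16x16
    dec2: up x2, concat enc2, conv3x3 (6w -> 2w)
    dec1: up x2, concat enc1, conv3x3 (3w -> w)
    head: conv1x1 (w -> 2 classes)

Default base width ``w = 8``.  One convolution per resolution level keeps a
full training run tractable on a single CPU core while remaining ample for
bright blob-like lesions; width and input channel count are constructor
arguments, so the same class serves the 1-, 3- and 4-channel ablation arms.
Initialisation is He-normal from a seeded generator, so two models built
with the same seed have identical weights.
"""

from __future__ import annotations

import pickle

import numpy as np

from ._nn import Adam, Conv2d, MaxPool2, ReLU, Upsample2, softmax_cross_entropy

SUPPORTED_CHANNELS = (1, 3, 4)


class UNet:
    def __init__(self, channels: int, base_width: int = 8, seed: int = 0):
        if channels not in SUPPORTED_CHANNELS:
            raise ValueError(f"channels must be one of {SUPPORTED_CHANNELS}")
        self.channels = channels
        self.base_width = base_width
        self.seed = seed
        rng = np.random.default_rng(seed)
        w = base_width
        self.enc1 = Conv2d(channels, w, 3, rng)
        self.enc2 = Conv2d(w, 2 * w, 3, rng)
        self.bott = Conv2d(2 * w, 4 * w, 3, rng)
        self.dec2 = Conv2d(6 * w, 2 * w, 3, rng)
        self.dec1 = Conv2d(3 * w, w, 3, rng)
        self.head = Conv2d(w, 2, 1, rng)
        self._convs = [self.enc1, self.enc2, self.bott, self.dec2, self.dec1, self.head]
        self._relus = [ReLU() for _ in range(5)]
        self._pools = [MaxPool2(), MaxPool2()]
        self._up = Upsample2()

    @property
    def params(self):
        return [p for conv in self._convs for p in conv.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, C, H, W) float32 in [0, 1]; H, W divisible by 4."""
        r = self._relus
        e1 = r[0].forward(self.enc1.forward(x))
        p1 = self._pools[0].forward(e1)
        e2 = r[1].forward(self.enc2.forward(p1))
        p2 = self._pools[1].forward(e2)
        bt = r[2].forward(self.bott.forward(p2))
        u2 = np.concatenate([self._up.forward(bt), e2], axis=1)
        d2 = r[3].forward(self.dec2.forward(u2))
        u1 = np.concatenate([self._up.forward(d2), e1], axis=1)
        d1 = r[4].forward(self.dec1.forward(u1))
        self._shapes = (e1.shape[1], e2.shape[1], bt.shape[1], d2.shape[1])
        return self.head.forward(d1)

    def backward(self, dlogits: np.ndarray):
        """Gradients of all conv parameters, ordered like ``self.params``."""
        r = self._relus
        w = self.base_width
        d, g_head = self.head.backward(dlogits)
        d, g_dec1 = self.dec1.backward(r[4].backward(d))
        d_up1, d_e1 = d[:, : 2 * w], d[:, 2 * w :]
        d = self._up.backward(d_up1)
        d, g_dec2 = self.dec2.backward(r[3].backward(d))
        d_up2, d_e2 = d[:, : 4 * w], d[:, 4 * w :]
        d = self._up.backward(d_up2)
        d, g_bott = self.bott.backward(r[2].backward(d))
        d = self._pools[1].backward(d) + d_e2
        d, g_enc2 = self.enc2.backward(r[1].backward(d))
        d = self._pools[0].backward(d) + d_e1
        _, g_enc1 = self.enc1.backward(r[0].backward(d))
        return g_enc1 + g_enc2 + g_bott + g_dec2 + g_dec1 + g_head

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        logits = self.forward(x)
        loss, dlogits, prob = softmax_cross_entropy(logits, y)
        grads = self.backward(dlogits.astype(np.float32))
        acc = float((prob.argmax(axis=1) == y).mean())
        return loss, grads, acc

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class map (B, H, W) in {0, 1}."""
        return self.forward(x).argmax(axis=1)

    def evaluate(self, x: np.ndarray, y: np.ndarray, batch_size: int = 8):
        """Mean cross-entropy loss and pixel accuracy over a dataset."""
        losses, accs, ns = [], [], []
        for i in range(0, len(x), batch_size):
            xb, yb = x[i : i + batch_size], y[i : i + batch_size]
            loss, _, prob = softmax_cross_entropy(self.forward(xb), yb)
            losses.append(loss)
            accs.append(float((prob.argmax(axis=1) == yb).mean()))
            ns.append(len(xb))
        n = np.array(ns, dtype=float)
        return float(np.average(losses, weights=n)), float(np.average(accs, weights=n))

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params, lr=lr)

    def save(self, path):
        state = {
            "channels": self.channels,
            "base_width": self.base_width,
            "seed": self.seed,
            "weights": [p.copy() for p in self.params],
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path) -> "UNet":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        model = cls(state["channels"], state["base_width"], state["seed"])
        for p, saved in zip(model.params, state["weights"]):
            p[...] = saved
        return model


def build_model(channels: int, base_width: int = 8, seed: int = 0) -> UNet:
    """Construct a compact U-Net for the given input channel count."""
    return UNet(channels=channels, base_width=base_width, seed=seed)
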