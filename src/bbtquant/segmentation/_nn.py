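"""Minimal CPU neural-network layers (numpy, float32) for the compact U-Net.

Only what the segmentation model needs: same-padded 3x3 / 1x1 convolutions
via im2col and matmul, ReLU, 2x2 max pooling, 2x nearest-neighbour
upsampling, channel concatenation, softmax cross-entropy, and Adam.  Arrays
are channel-first ``(B, C, H, W)``.  Everything is deterministic: parameter
initialisation draws from a caller-supplied generator and the forward/backward
passes are plain numpy.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patch matrix with same padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) -> (B, H, W, C, k, k)
    b, c, h, w = x.shape
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, h * w, c * k * k)


class Conv2d:
    """Same-padded convolution with bias; kernel size 3 or 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.W = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.W.T + self.b
        self._cache = (cols, (b, c, h, w))
        return out.transpose(0, 2, 1).reshape(b, self.c_out, h, w)

    def backward(self, dout: np.ndarray):
        cols, (b, c, h, w) = self._cache
        dflat = dout.reshape(b, self.c_out, h * w).transpose(0, 2, 1)  # (B, HW, Cout)
        dW = np.einsum("bpo,bpi->oi", dflat, cols, optimize=True)
        db = dflat.sum(axis=(0, 1))
        # gradient wrt input = convolution of dout with the flipped kernel
        Wk = self.W.reshape(self.c_out, self.c_in, self.k, self.k)
        Wflip = Wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            self.c_in, self.c_out * self.k * self.k
        )
        dcols = _im2col(dout.astype(np.float32), self.k)
        dx = (dcols @ Wflip.T).transpose(0, 2, 1).reshape(b, self.c_in, h, w)
        return dx, [dW.astype(np.float32), db.astype(np.float32)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; input H, W must be even."""

    def __init__(self):
        self._cache = None

    def forward(self, x):
        b, c, h, w = x.shape
        r = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(b, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (b, c, h, w))
        return out

    def backward(self, dout):
        idx, (b, c, h, w) = self._cache
        dr = np.zeros((b, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(b, c, h, w)


class Upsample2:
    """2x nearest-neighbour upsampling; backward sums the 2x2 blocks."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        b, c, h, w = dout.shape
        return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean pixelwise 2-class cross-entropy and its gradient wrt logits.

    ``logits``: (B, n_classes, H, W); ``targets``: (B, H, W) integer labels.
    """
    b, nc, h, w = logits.shape
    shifted = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    prob = exp / exp.sum(axis=1, keepdims=True)
    onehot = np.eye(nc, dtype=logits.dtype)[targets].transpose(0, 3, 1, 2)
    n = b * h * w
    loss = float(-(onehot * np.log(prob + 1e-12)).sum() / n)
    grad = (prob - onehot) / n
    return loss, grad, prob


class Adam:
    """Standard Adam over a flat list of parameter arrays (updates in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
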