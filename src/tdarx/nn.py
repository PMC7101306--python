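"""Minimal convolutional network, in numpy, for colour-block rasters.

The classification task is deliberately easy for a CNN — the informative
content of a rendered record is a few dozen uniformly coloured rectangles —
so a compact network trained from scratch suffices: two convolution/pooling
stages followed by a small fully connected head.  Convolutions use im2col
and a single GEMM per layer; the optimiser is minibatch SGD with momentum
0.9 (the conventional default for this style of fine-tuning recipe).

Two backbones are exposed:

``SmallCNN``
    all layers trainable, He initialisation, trained from scratch.

``FrozenFeatureCNN``
    the same convolutional stack with frozen, seeded random weights; only
    the final fully connected layers are trained.  This mirrors the
    final-layer-replacement transfer-learning recipe (replace the head,
    keep the feature extractor) using fixed random convolutional features
    instead of downloaded pretrained weights.

Everything is deterministic given the construction seed and data order.
"""

from __future__ import annotations

import numpy as np


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    """(N,H,W,C) -> (N*OH*OW, k*k*C) patch matrix."""
    n, h, w, c = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, k, k, c),
        strides=(s0, s1 * stride, s2 * stride, s1, s2, s3), writeable=False)
    return windows.reshape(n * oh * ow, k * k * c), oh, ow


def _col2im(grad_cols: np.ndarray, x_shape, k: int, stride: int,
            oh: int, ow: int) -> np.ndarray:
    """Scatter-add patch gradients back onto the input tensor."""
    n, h, w, c = x_shape
    gx = np.zeros(x_shape, dtype=np.float32)
    cols = grad_cols.reshape(n, oh, ow, k, k, c)
    for di in range(k):
        for dj in range(k):
            gx[:, di:di + oh * stride:stride, dj:dj + ow * stride:stride] += \
                cols[:, :, :, di, dj]
    return gx


class _Conv:
    def __init__(self, rng, in_c, out_c, k, stride):
        self.k, self.stride = k, stride
        self.W = _he(rng, (k * k * in_c, out_c), k * k * in_c)
        self.b = np.zeros(out_c, dtype=np.float32)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x):
        cols, oh, ow = _im2col(x, self.k, self.stride)
        out = cols @ self.W + self.b
        self._cache = (x.shape, cols, oh, ow)
        return out.reshape(x.shape[0], oh, ow, -1)

    def backward(self, grad):
        x_shape, cols, oh, ow = self._cache
        g = grad.reshape(-1, grad.shape[-1])
        self.gW = cols.T @ g
        self.gb = g.sum(axis=0)
        return _col2im(g @ self.W.T, x_shape, self.k, self.stride, oh, ow)

    def step(self, lr, momentum):
        self.vW = momentum * self.vW - lr * self.gW
        self.vb = momentum * self.vb - lr * self.gb
        self.W += self.vW
        self.b += self.vb


class _Dense:
    def __init__(self, rng, n_in, n_out):
        self.W = _he(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T

    def step(self, lr, momentum):
        self.vW = momentum * self.vW - lr * self.gW
        self.vb = momentum * self.vb - lr * self.gb
        self.W += self.vW
        self.b += self.vb


def _relu_fwd(x):
    return np.maximum(x, 0.0)


def _maxpool2(x):
    """2x2, stride 2 max pool (odd trailing row/col cropped)."""
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, :h2 * 2, :w2 * 2]
    xr = xc.reshape(n, h2, 2, w2, 2, c)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None, :]
    return out, (mask, x.shape)


def _maxpool2_back(grad, cache):
    mask, x_shape = cache
    n, h2, _, w2, _, c = mask.shape
    g = mask * grad[:, :, None, :, None, :]
    gx = np.zeros(x_shape, dtype=np.float32)
    gx[:, :h2 * 2, :w2 * 2] = g.reshape(n, h2 * 2, w2 * 2, c)
    return gx


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """conv(5x5/4,12) - pool - conv(3x3,16) - pool - fc32 - fc2."""

    train_conv = True

    def __init__(self, input_hw: tuple[int, int], seed: int = 0,
                 lr: float = 0.001, momentum: float = 0.9):
        rng = np.random.default_rng(seed)
        self.lr, self.momentum = lr, momentum
        h, w = input_hw
        self.conv1 = _Conv(rng, 3, 12, k=5, stride=4)
        h1, w1 = (h - 5) // 4 + 1, (w - 5) // 4 + 1
        h1p, w1p = h1 // 2, w1 // 2
        self.conv2 = _Conv(rng, 12, 16, k=3, stride=1)
        h2, w2 = h1p - 2, w1p - 2
        h2p, w2p = h2 // 2, w2 // 2
        self.n_flat = h2p * w2p * 16
        if self.n_flat <= 0:
            raise ValueError(f"input {input_hw} too small for this network")
        self.fc1 = _Dense(rng, self.n_flat, 32)
        self.fc2 = _Dense(rng, 32, 2)
        self.input_hw = (h, w)

    # -- forward / backward -------------------------------------------------
    def _features(self, x):
        a1 = _relu_fwd(self.conv1.forward(x))
        p1, c1 = _maxpool2(a1)
        a2 = _relu_fwd(self.conv2.forward(p1))
        p2, c2 = _maxpool2(a2)
        flat = p2.reshape(x.shape[0], -1)
        self._fcache = (a1, c1, a2, c2, p2.shape)
        return flat

    def forward(self, x):
        flat = self._features(x)
        z1 = self.fc1.forward(flat)
        a3 = _relu_fwd(z1)
        self._hcache = (z1, a3)
        return self.fc2.forward(a3)

    def backward(self, grad_logits):
        z1, a3 = self._hcache
        g = self.fc2.backward(grad_logits)
        g = g * (z1 > 0)
        g = self.fc1.backward(g)
        if not self.train_conv:
            return
        a1, c1, a2, c2, p2_shape = self._fcache
        g = g.reshape(p2_shape)
        g = _maxpool2_back(g, c2)
        g = g * (a2 > 0)
        g = self.conv2.backward(g)
        g = _maxpool2_back(g, c1)
        g = g * (a1 > 0)
        self.conv1.backward(g)

    def _step(self):
        self.fc1.step(self.lr, self.momentum)
        self.fc2.step(self.lr, self.momentum)
        if self.train_conv:
            self.conv1.step(self.lr, self.momentum)
            self.conv2.step(self.lr, self.momentum)

    # -- training interface -------------------------------------------------
    def train_batch(self, x, y) -> float:
        """One SGD step on a minibatch; returns the mean cross-entropy."""
        logits = self.forward(x)
        p = _softmax(logits)
        n = x.shape[0]
        loss = float(-np.log(p[np.arange(n), y] + 1e-12).mean())
        grad = p
        grad[np.arange(n), y] -= 1.0
        self.backward(grad.astype(np.float32) / n)
        self._step()
        return loss

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        if x.shape[0] == 0:
            return np.zeros((0, 2), dtype=np.float32)
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(_softmax(self.forward(x[i:i + batch_size])))
        return np.concatenate(outs, axis=0)


class FrozenFeatureCNN(SmallCNN):
    """SmallCNN with frozen (seeded random) convolutions; only the fully
    connected head is trained — the final-layer-replacement recipe."""

    train_conv = False


BACKBONES = {"small_cnn": SmallCNN, "pretrained_transfer": FrozenFeatureCNN}
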