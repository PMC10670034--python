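"""Minimal NumPy convolutional-network engine backing the desk-scale classifier.

Implements exactly the pieces the binary classifier needs: 3x3 same-padding
convolutions (im2col as matrix products), ReLU, 2x2 max pooling, global average
pooling, a single-logit dense head, sigmoid/binary cross-entropy with logits,
and SGD with momentum. All state is plain float64 ndarrays so checkpoints are
portable .npz files.

Shapes follow the (batch, channels, height, width) convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, H, W, C*9) patches of the zero-padded input."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B, C, H, W, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        x.shape[0], x.shape[2], x.shape[3], -1)


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1 (spatial-size preserving)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialization
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None

    def forward(self, x, train=False):
        cols = _im2col3(x)
        if train:
            self._cols = cols
        wmat = self.w.reshape(self.w.shape[0], -1)
        y = cols @ wmat.T + self.b
        return y.transpose(0, 3, 1, 2)

    def backward(self, dy):
        b, c_out, h, w = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, c_out)
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.dw[...] = (dyf.T @ cols).reshape(self.w.shape)
        self.db[...] = dyf.sum(axis=0)
        # dX = correlation of dY with spatially flipped kernels, summed over c_out
        wflip = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in, c_out, 3, 3)
        dcols = _im2col3(dy)  # (B, H, W, c_out*9)
        dx = dcols @ wflip.reshape(wflip.shape[0], -1).T
        self._cols = None
        return dx.transpose(0, 3, 1, 2)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling with stride 2; requires even spatial dimensions."""

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        tiles = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        tiles = tiles.reshape(b, c, h // 2, w // 2, 4)
        if train:
            self._idx = tiles.argmax(axis=-1)
            self._shape = (b, c, h, w)
        return tiles.max(axis=-1)

    def backward(self, dy):
        b, c, h, w = self._shape
        grad = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(grad, self._idx[..., None], dy[..., None], axis=-1)
        grad = grad.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return grad.reshape(b, c, h, w)

    def params(self):
        return []


class GlobalAvgPool:
    def forward(self, x, train=False):
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        h, w = self._spatial
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               dy.shape + (h, w)).copy()

    def params(self):
        return []


class DenseLogit:
    """Single-output linear head: features (B, F) -> logits (B,)."""

    def __init__(self, n_features: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, 1.0 / np.sqrt(n_features), size=n_features)
        self.b = np.zeros(1)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, feat, train=False):
        if train:
            self._feat = feat
        return feat @ self.w + self.b[0]

    def backward(self, dlogit):
        self.dw[...] = dlogit @ self._feat
        self.db[...] = dlogit.sum()
        return np.outer(dlogit, self.w)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class SmallCNN:
    """3 conv/pool blocks + 1 conv block -> global average pool -> single logit.

    The global-average-pooled activations are the penultimate feature vector
    (``feature_dim`` = channels of the last conv). The input side must be a
    multiple of 8 (three 2x2 pools).
    """

    def __init__(self, input_side: int = 64, channels=(8, 16, 32, 256), seed: int = 0):
        if input_side % 8 != 0 or input_side < 16:
            raise ValueError("input_side must be a multiple of 8 and >= 16")
        rng = np.random.default_rng([seed, 0xC0])
        self.input_side = input_side
        self.channels = tuple(channels)
        self.feature_dim = channels[-1]
        self.blocks = []
        c_prev = 3
        for i, c in enumerate(channels):
            self.blocks.append(Conv3x3(c_prev, c, rng))
            self.blocks.append(ReLU())
            if i < 3:
                self.blocks.append(MaxPool2())
            c_prev = c
        self.gap = GlobalAvgPool()
        self.head = DenseLogit(self.feature_dim, rng)

    def forward(self, x: np.ndarray, train: bool = False):
        """x: (B, side, side, 3) in [0, 1] -> (logits (B,), features (B, F)).

        Inputs are centered to [-0.5, 0.5] before the first convolution; a
        zero-mean input keeps first-layer gradients balanced, which matters
        when the discriminative color contrast is subtle.
        """
        z = np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=np.float64) - 0.5
        for layer in self.blocks:
            z = layer.forward(z, train=train)
        feat = self.gap.forward(z, train=train)
        logit = self.head.forward(feat, train=train)
        return logit, feat

    def backward(self, dlogit: np.ndarray) -> None:
        d = self.head.backward(dlogit)
        d = self.gap.backward(d)
        for layer in reversed(self.blocks):
            d = layer.backward(d)

    def params(self):
        out = []
        for layer in self.blocks:
            out.extend(layer.params())
        out.extend(self.head.params())
        return out

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, (p, _) in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (p, _) in enumerate(self.params()):
            p[...] = state[f"p{i}"]


def sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=np.float64)))


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    z, y = np.asarray(logits, dtype=np.float64), np.asarray(targets, dtype=np.float64)
    loss = np.mean(np.logaddexp(0.0, z) - y * z)
    dlogits = (sigmoid(z) - y) / z.size
    return loss, dlogits


class SGDMomentum:
    def __init__(self, params, lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p, _ in params]

    def step(self):
        for v, (p, g) in zip(self.velocity, self.params):
            v *= self.momentum
            v += g
            p -= self.lr * v
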