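"""Minimal NumPy neural-network engine used by the behavior classifier.

Implements exactly the pieces the detection network needs: 3x3 'same'
convolution, ReLU, 2x2 stride-2 max pooling with ceil-mode output sizes,
a dense layer, softmax cross-entropy, and the Adam optimizer.  All
arithmetic is float32; forward activations needed for backprop are
cached on the layer between ``forward`` and ``backward`` calls.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3x3",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def glorot_uniform(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int
) -> np.ndarray:
    """Glorot/Xavier uniform initialization; keeps initial logits small
    enough for stable training at the large initial learning rate."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv3x3:
    """3x3 convolution, stride 1, zero 'same' padding (NHWC layout)."""

    def __init__(self, rng: np.random.Generator, in_ch: int, out_ch: int):
        self.W = glorot_uniform(rng, (9 * in_ch, out_ch), 9 * in_ch, 9 * out_ch)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.in_ch = in_ch
        self.out_ch = out_ch

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # n,h,w,c,3,3
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, 9 * c)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        out = (cols @ self.W + self.b).reshape(n, h, w, self.out_ch)
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, _ = dout.shape
        dflat = dout.reshape(n * h * w, self.out_ch).astype(np.float32)
        self.dW += self._cols.T @ dflat
        self.db += dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(n, h, w, 3, 3, self.in_ch)
        dxp = np.zeros((n, h + 2, w + 2, self.in_ch), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        del self._cols
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; odd inputs are ceil-padded with -inf so
    the output side is ``ceil(side / 2)`` (100 -> 50 -> 25 -> 13)."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        ph, pw = (-h) % 2, (-w) % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), constant_values=-np.inf)
        h2, w2 = x.shape[1] // 2, x.shape[2] // 2
        tiles = x.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        idx = np.argmax(tiles, axis=-1)
        out = np.take_along_axis(tiles, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._in_shape = (n, h, w, c)
            self._pad = (ph, pw)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        ph, pw = self._pad
        h2, w2 = dout.shape[1], dout.shape[2]
        dtiles = np.zeros((n, h2, w2, c, 4), dtype=np.float32)
        np.put_along_axis(dtiles, self._idx[..., None], dout[..., None].astype(np.float32), axis=-1)
        dx = dtiles.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(
            n, 2 * h2, 2 * w2, c
        )
        return dx[:, : h, : w, :]


class Flatten:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int):
        self.W = glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x.astype(np.float32) @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout.astype(np.float32)
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        del self._x
        return dout @ self.W.T


class Sequential:
    """A plain layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def zero_grad(self) -> None:
        for _, g in self.params:
            g.fill(0.0)

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params
        if len(own) != len(weights):
            raise ValueError("weight list does not match the architecture")
        for (p, _), w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. logits.

    Returns ``(loss, dlogits, probs)``; ``dlogits`` is already divided
    by the batch size.
    """
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32), probs


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, lr: float = 0.01, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p, _ in params]
            self._v = [np.zeros_like(p) for p, _ in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(params, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
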