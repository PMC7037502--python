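"""Neural-network layers with explicit forward/backward passes.

Everything is plain numpy.  Convolutions are cross-correlations with stride 1
and no padding ('valid'); pooling uses non-overlapping windows of the pool
width, dropping any trailing remainder shorter than one window.  Dropout is
the inverted variant, so evaluation-mode forward passes need no rescaling.

Conventions
-----------
* conv1d input: (batch, channels, length); conv2d input: (batch, channels, H, W)
* each layer exposes ``params`` / ``grads`` (aligned lists of arrays) and
  ``forward(x, training)`` / ``backward(dout) -> dx``
* weights initialise from a seeded uniform(-1, 1) / sqrt(fan_in) scheme
  ("small random numbers"); biases start at zero
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv1d",
    "Conv2d",
    "Pool1d",
    "Pool2d",
    "ReLU",
    "Flatten",
    "Dense",
    "Dropout",
    "relu",
    "softmax",
]


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(x, 0.0)


def softmax(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Exponential normalisation to a probability distribution.

    Shift-invariant (the max is subtracted before exponentiation), so large
    scores do not overflow; output sums to 1 along ``axis``.
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    z = v - np.max(v, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _init_weight(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.uniform(-1.0, 1.0, size=shape) / np.sqrt(fan_in)).astype(dtype)


class Layer:
    """Base layer: parameter-free, identity-like interface."""

    frozen: bool = False

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv1d(Layer):
    """1-D valid cross-correlation: out[o, t] = sum_{c,x} in[c, t+x] w[o,c,x] + b[o]."""

    def __init__(self, in_channels: int, out_channels: int, width: int,
                 rng: np.random.Generator, dtype=np.float32):
        if width < 1:
            raise ValueError("kernel width must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.width = width
        fan_in = in_channels * width
        self.W = _init_weight(rng, (out_channels, in_channels, width), fan_in, dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._windows: np.ndarray | None = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"conv1d expected {self.in_channels} channels, got {x.shape[1]}")
        if x.shape[2] < self.width:
            raise ValueError(
                f"conv1d input length {x.shape[2]} shorter than kernel width {self.width}"
            )
        windows = sliding_window_view(x, self.width, axis=2)  # (N, C, L_out, m)
        self._windows = windows if training else None
        self._in_len = x.shape[2]
        out = np.einsum("nclm,ocm->nol", windows, self.W, optimize=True)
        return out + self.b[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        windows = self._windows
        self.dW[...] = np.einsum("nclm,nol->ocm", windows, dout, optimize=True)
        self.db[...] = dout.sum(axis=(0, 2))
        # dx[c, l] = sum_{o, x} dout[o, l - x] W[o, c, x]  (full correlation)
        m = self.width
        pad = np.pad(dout, ((0, 0), (0, 0), (m - 1, m - 1)))
        pwin = sliding_window_view(pad, m, axis=2)  # (N, O, L_in, m)
        W_rev = self.W[:, :, ::-1]
        return np.einsum("nolm,ocm->ncl", pwin, W_rev, optimize=True)


class Conv2d(Layer):
    """2-D valid cross-correlation with per-kernel bias."""

    def __init__(self, in_channels: int, out_channels: int, height: int, width: int,
                 rng: np.random.Generator, dtype=np.float32):
        if height < 1 or width < 1:
            raise ValueError("kernel dims must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.height = height
        self.width = width
        fan_in = in_channels * height * width
        self.W = _init_weight(rng, (out_channels, in_channels, height, width), fan_in, dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._windows = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"conv2d expected {self.in_channels} channels, got {x.shape[1]}")
        if x.shape[2] < self.height or x.shape[3] < self.width:
            raise ValueError(
                f"conv2d input {x.shape[2]}x{x.shape[3]} smaller than "
                f"kernel {self.height}x{self.width}"
            )
        windows = sliding_window_view(x, (self.height, self.width), axis=(2, 3))
        # windows: (N, C, H_out, W_out, kh, kw)
        self._windows = windows if training else None
        out = np.einsum("nchwij,ocij->nohw", windows, self.W, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        windows = self._windows
        self.dW[...] = np.einsum("nchwij,nohw->ocij", windows, dout, optimize=True)
        self.db[...] = dout.sum(axis=(0, 2, 3))
        kh, kw = self.height, self.width
        pad = np.pad(dout, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        pwin = sliding_window_view(pad, (kh, kw), axis=(2, 3))  # (N, O, H_in, W_in, kh, kw)
        W_rev = self.W[:, :, ::-1, ::-1]
        return np.einsum("nohwij,ocij->nchw", pwin, W_rev, optimize=True)


class Pool1d(Layer):
    """Non-overlapping max or average pooling; trailing remainder dropped."""

    def __init__(self, width: int, mode: str = "max"):
        if width < 1:
            raise ValueError("pool width must be >= 1")
        if mode not in ("max", "avg"):
            raise ValueError(f"pool mode must be 'max' or 'avg', got {mode!r}")
        self.width = width
        self.mode = mode

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        w = self.width
        n_out = x.shape[-1] // w
        if n_out < 1:
            raise ValueError(f"input length {x.shape[-1]} shorter than pool width {w}")
        self._in_len = x.shape[-1]
        blocks = x[..., : n_out * w].reshape(*x.shape[:-1], n_out, w)
        if self.mode == "max":
            self._argmax = blocks.argmax(axis=-1)
            return blocks.max(axis=-1)
        self._shape = blocks.shape
        return blocks.mean(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w = self.width
        n_out = dout.shape[-1]
        blocks = np.zeros(dout.shape + (w,), dtype=dout.dtype)
        if self.mode == "max":
            np.put_along_axis(blocks, self._argmax[..., None], dout[..., None], axis=-1)
        else:
            blocks[...] = dout[..., None] / w
        dx = np.zeros(dout.shape[:-1] + (self._in_len,), dtype=dout.dtype)
        dx[..., : n_out * w] = blocks.reshape(*dout.shape[:-1], n_out * w)
        return dx


class Pool2d(Layer):
    """Square non-overlapping max/avg pooling on (N, C, H, W)."""

    def __init__(self, width: int, mode: str = "max"):
        if width < 1:
            raise ValueError("pool width must be >= 1")
        if mode not in ("max", "avg"):
            raise ValueError(f"pool mode must be 'max' or 'avg', got {mode!r}")
        self.width = width
        self.mode = mode

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        w = self.width
        n, c, h, wd = x.shape
        ho, wo = h // w, wd // w
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{wd} smaller than pool window {w}x{w}")
        self._in_shape = x.shape
        blocks = x[:, :, : ho * w, : wo * w].reshape(n, c, ho, w, wo, w)
        blocks = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, w * w)
        if self.mode == "max":
            self._argmax = blocks.argmax(axis=-1)
            return blocks.max(axis=-1)
        return blocks.mean(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w = self.width
        n, c, h, wd = self._in_shape
        ho, wo = dout.shape[2], dout.shape[3]
        flat = np.zeros((n, c, ho, wo, w * w), dtype=dout.dtype)
        if self.mode == "max":
            np.put_along_axis(flat, self._argmax[..., None], dout[..., None], axis=-1)
        else:
            flat[...] = dout[..., None] / (w * w)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        blocks = flat.reshape(n, c, ho, wo, w, w).transpose(0, 1, 2, 4, 3, 5)
        dx[:, :, : ho * w, : wo * w] = blocks.reshape(n, c, ho * w, wo * w)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer: y = x W + b, W of shape (in, out)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.in_features = in_features
        self.out_features = out_features
        self.W = _init_weight(rng, (in_features, out_features), in_features, dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ValueError(
                f"dense layer expected {self.in_features} inputs, got {x.shape[1]}"
            )
        self._x = x if training else None
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout: active only in training mode; identity at evaluation."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask
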