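"""Minimal CPU layer primitives with explicit backward passes.

Tensors are float32 arrays laid out channels-first, ``(C, H, W)``, one sample
at a time.  Convolutions run as im2col + matmul; the transposed convolution
scatters per-position kernel patches (its input grids are tiny at stride 32).
Each layer caches what its backward pass needs and accumulates parameter
gradients in ``.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "MaxPool2x2Ceil", "ReLU", "Dropout",
           "ConvTranspose2d", "CenterOffsetCrop"]


class Layer:
    """Base: forward(x, train) -> y; backward(dy) -> dx."""

    def params(self):
        return {}

    @property
    def grads(self):
        return getattr(self, "_grads", {})

    def zero_grad(self):
        for g in self.grads.values():
            g[...] = 0.0


class Conv2d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.padding = padding
        self.W = np.zeros((out_channels, in_channels, kernel_size, kernel_size),
                          dtype=np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self._grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}

    def params(self):
        return {"W": self.W, "b": self.b}

    def out_size(self, n: int) -> int:
        return (n + 2 * self.padding - self.k) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, h, w = x.shape
        p, k, s = self.padding, self.k, self.stride
        if p:
            xp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=np.float32)
            xp[:, p:-p, p:-p] = x
        else:
            xp = x
        ho, wo = self.out_size(h), self.out_size(w)
        if ho < 1 or wo < 1:
            raise ValueError(
                f"conv {k}x{k} input {h}x{w} (pad {p}) has no valid output")
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        cols = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        y = cols @ self.W.reshape(self.out_channels, -1).T + self.b
        self._cache = (cols, (c, h, w))
        return y.T.reshape(self.out_channels, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (c, h, w) = self._cache
        p, k, s = self.padding, self.k, self.stride
        co, ho, wo = dy.shape
        dym = dy.reshape(co, ho * wo).T.astype(np.float32)
        self._grads["W"] += (dym.T @ cols).reshape(self.W.shape)
        self._grads["b"] += dym.sum(axis=0)
        dcols = dym @ self.W.reshape(co, -1)
        dcols = dcols.reshape(ho, wo, c, k, k).transpose(3, 4, 2, 0, 1)
        dxp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for u in range(k):
            for v in range(k):
                dxp[:, u:u + s * ho:s, v:v + s * wo:s] += dcols[u, v]
        return dxp[:, p:p + h, p:p + w] if p else dxp


class MaxPool2x2Ceil(Layer):
    """2x2 stride-2 max pooling with ceil-mode output sizing.

    Odd extents are padded with -inf on the bottom/right so the last window
    covers the remaining row/column alone.
    """

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, h, w = x.shape
        ho, wo = -(-h // 2), -(-w // 2)
        xp = np.full((c, 2 * ho, 2 * wo), -np.inf, dtype=np.float32)
        xp[:, :h, :w] = x
        r = xp.reshape(c, ho, 2, wo, 2).transpose(0, 1, 3, 2, 4).reshape(c, ho, wo, 4)
        idx = r.argmax(axis=3)
        y = np.take_along_axis(r, idx[..., None], axis=3)[..., 0]
        self._cache = (idx, (c, h, w), (ho, wo))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (c, h, w), (ho, wo) = self._cache
        dr = np.zeros((c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(dr, idx[..., None], dy[..., None], axis=3)
        dxp = dr.reshape(c, ho, wo, 2, 2).transpose(0, 1, 3, 2, 4).reshape(
            c, 2 * ho, 2 * wo)
        return dxp[:, :h, :w]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Needs a bound RNG for training."""

    def __init__(self, rate: float = 0.5):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without an RNG")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class ConvTranspose2d(Layer):
    """Transposed convolution (learned upsampling), no bias.

    Output side = (in - 1) * stride + kernel.  Weights are stored
    ``(C_in, C_out, k, k)`` as in the convolution it transposes.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.W = np.zeros((in_channels, out_channels, kernel_size, kernel_size),
                          dtype=np.float32)
        self._grads = {"W": np.zeros_like(self.W)}

    def params(self):
        return {"W": self.W}

    def out_size(self, n: int) -> int:
        return (n - 1) * self.stride + self.k

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, h, w = x.shape
        k, s = self.k, self.stride
        ho, wo = self.out_size(h), self.out_size(w)
        y = np.zeros((self.out_channels, ho, wo), dtype=np.float32)
        wmat = self.W.reshape(c, -1)  # (C_in, C_out*k*k)
        patches = (x.reshape(c, h * w).T @ wmat).reshape(h, w, self.out_channels, k, k)
        for i in range(h):
            for j in range(w):
                y[:, i * s:i * s + k, j * s:j * s + k] += patches[i, j]
        self._cache = (x, (ho, wo))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, _ = self._cache
        c, h, w = x.shape
        k, s = self.k, self.stride
        # gather the k x k output patch under each input position
        patches = np.empty((h, w, self.out_channels, k, k), dtype=np.float32)
        for i in range(h):
            for j in range(w):
                patches[i, j] = dy[:, i * s:i * s + k, j * s:j * s + k]
        pm = patches.reshape(h * w, -1)  # (HW, C_out*k*k)
        self._grads["W"] += (x.reshape(c, h * w) @ pm).reshape(self.W.shape)
        dx = (pm @ self.W.reshape(c, -1).T).T.reshape(c, h, w)
        return dx


class CenterOffsetCrop(Layer):
    """Crop a fixed offset window down to the target spatial size."""

    def __init__(self, offset: int):
        self.offset = offset
        self.target: tuple[int, int] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.target is None:
            raise RuntimeError("crop target size not set")
        th, tw = self.target
        o = self.offset
        c, h, w = x.shape
        if h < th + o or w < tw + o:
            raise ValueError(f"cannot crop {h}x{w} to {th}x{tw} at offset {o}")
        self._in_shape = (c, h, w)
        return x[:, o:o + th, o:o + tw]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._in_shape
        o = self.offset
        dx = np.zeros((c, h, w), dtype=np.float32)
        dx[:, o:o + dy.shape[1], o:o + dy.shape[2]] = dy
        return dx
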