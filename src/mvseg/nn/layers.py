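"""Trainable layers: 2D convolution, 2x2 max-pool, ReLU, 2x2 transposed conv.

All tensors are NHWC float32.  Convolutions are computed as a sum over kernel
offsets of batched channel matmuls — for 3x3 kernels that is nine GEMMs, which
BLAS handles far faster than any explicit im2col copy at these sizes.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """A layer with optional trainable parameters."""

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(value, gradient) pairs; empty for parameter-free layers."""
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded k x k convolution with bias, He-normal initialization."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        bias_init: float = 0.0,
    ) -> None:
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, k, c_in, c_out)).astype(
            np.float32
        )
        self.b = np.full(c_out, bias_init, dtype=np.float32)
        self.k = k
        self.pad = k // 2
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xp = xp
        n, hp, wp, _ = xp.shape
        h, w = hp - 2 * p, wp - 2 * p
        out = np.empty((n, h, w, self.b.size), dtype=np.result_type(xp, self.w))
        out[...] = self.b
        for di in range(self.k):
            for dj in range(self.k):
                out += self._xp[:, di : di + h, dj : dj + w, :] @ self.w[di, dj]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        p = self.pad
        h, w = dout.shape[1], dout.shape[2]
        dxp = np.zeros_like(xp)
        for di in range(self.k):
            for dj in range(self.k):
                xs = xp[:, di : di + h, dj : dj + w, :]
                self.dw[di, dj] = np.tensordot(xs, dout, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di : di + h, dj : dj + w, :] += dout @ self.w[di, dj].T
        self.db[...] = dout.sum(axis=(0, 1, 2))
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; gradient routed to the (first) argmax."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {(h, w)}")
        win = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        self._idx = win.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        dwin = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, self._idx[..., None], dout[..., None], axis=-1)
        return (
            dwin.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class UpConv2(Layer):
    """2x2 transposed convolution with stride 2 (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        self.w = rng.normal(0.0, np.sqrt(2.0 / c_in), (2, 2, c_in, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, h, w, _ = x.shape
        out = np.empty((n, 2 * h, 2 * w, self.b.size), dtype=np.result_type(x, self.w))
        for a in range(2):
            for b in range(2):
                out[:, a::2, b::2, :] = x @ self.w[a, b]
        out += self.b
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        dx = np.zeros_like(x)
        for a in range(2):
            for b in range(2):
                d = dout[:, a::2, b::2, :]
                self.dw[a, b] = np.tensordot(x, d, axes=([0, 1, 2], [0, 1, 2]))
                dx += d @ self.w[a, b].T
        self.db[...] = dout.sum(axis=(0, 1, 2))
        return dx
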