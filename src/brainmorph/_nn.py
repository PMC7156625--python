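"""Minimal 3-D neural-network engine on numpy.

Implements exactly the layer zoo the morphometry network needs — strided 3-D
convolution with boundary-preserving (TF "SAME") padding, unpadded max
pooling, fully connected layers, ReLU, dropout — with hand-written backward
passes and an Adam optimizer.  Convolutions are evaluated as im2col + GEMM so
the heavy lifting runs in BLAS.

Array layout is channels-first: ``(N, C, D, H, W)``.  float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3dSame",
    "MaxPool3d",
    "Flatten",
    "Dense",
    "ReLU",
    "Dropout",
    "Sequential",
    "Adam",
    "conv_same_out_edge",
    "pool_valid_out_edge",
]


def conv_same_out_edge(n: int, stride: int) -> int:
    """Boundary-preserving convolution output edge: ceil(n / stride)."""
    return -(-n // stride)


def pool_valid_out_edge(n: int, kernel: int, stride: int) -> int:
    """Unpadded pooling output edge: floor((n - k)/stride) + 1."""
    return (n - kernel) // stride + 1


def _same_pad(n: int, k: int, s: int) -> tuple[int, int]:
    out = conv_same_out_edge(n, s)
    total = max((out - 1) * s + k - n, 0)
    lo = total // 2
    return lo, total - lo


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3dSame(Layer):
    """Cubic-kernel strided 3-D convolution with SAME padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, needs_input_grad: bool = True):
        fan_in = c_in * kernel**3
        fan_out = c_out * kernel**3
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Xavier/Glorot uniform
        self.w = rng.uniform(-limit, limit, size=(c_out, c_in, kernel, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = kernel
        self.stride = stride
        self.needs_input_grad = needs_input_grad
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        k, s = self.kernel, self.stride
        pads = [_same_pad(e, k, s) for e in (d, h, w)]
        xp = np.pad(x, [(0, 0), (0, 0)] + pads)
        self._padded_shape = xp.shape
        self._pads = pads
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        od, oh, ow = win.shape[2:5]
        # (N, O³, C·k³) with channel-major patch layout
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            n, od * oh * ow, c * k**3
        )
        self._cols = cols
        w_mat = self.w.reshape(self.w.shape[0], -1)
        out = cols @ w_mat.T + self.b
        self._out_spatial = (od, oh, ow)
        return np.ascontiguousarray(
            out.reshape(n, od, oh, ow, -1).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        n = dy.shape[0]
        c_out = self.w.shape[0]
        od, oh, ow = self._out_spatial
        dy_mat = dy.transpose(0, 2, 3, 4, 1).reshape(n, od * oh * ow, c_out)
        w_mat = self.w.reshape(c_out, -1)
        dw_mat = np.einsum("npo,npq->oq", dy_mat, self._cols, optimize=True)
        self.dw[...] = dw_mat.reshape(self.w.shape)
        self.db[...] = dy_mat.sum(axis=(0, 1))
        if not self.needs_input_grad:
            return None
        k, s = self.kernel, self.stride
        c_in = self.w.shape[1]
        dcols = dy_mat @ w_mat  # (N, O³, C·k³)
        dcols = dcols.reshape(n, od * oh * ow, c_in, k**3).transpose(0, 2, 1, 3)
        _, _, pd, ph, pw = self._padded_shape
        idx = self._scatter_index(pd, ph, pw)
        dxp = np.zeros((n, c_in, pd * ph * pw), dtype=np.float32)
        flat = dcols.reshape(n, c_in, -1)
        for i in range(n):
            for j in range(c_in):
                np.add.at(dxp[i, j], idx, flat[i, j])
        dxp = dxp.reshape(n, c_in, pd, ph, pw)
        (d0, _), (h0, _), (w0, _) = self._pads
        d, h, w = (pd - sum(self._pads[0]), ph - sum(self._pads[1]), pw - sum(self._pads[2]))
        return dxp[:, :, d0:d0 + d, h0:h0 + h, w0:w0 + w]

    def _scatter_index(self, pd: int, ph: int, pw: int) -> np.ndarray:
        k, s = self.kernel, self.stride
        od, oh, ow = self._out_spatial
        oz = np.arange(od) * s
        oy = np.arange(oh) * s
        ox = np.arange(ow) * s
        kz, ky, kx = np.meshgrid(np.arange(k), np.arange(k), np.arange(k), indexing="ij")
        base = (oz[:, None, None] * ph * pw + oy[None, :, None] * pw + ox[None, None, :])
        off = (kz * ph * pw + ky * pw + kx).ravel()
        return (base.ravel()[:, None] + off[None, :]).ravel()


class MaxPool3d(Layer):
    def __init__(self, kernel: int, stride: int):
        self.kernel = kernel
        self.stride = stride

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s = self.kernel, self.stride
        n, c, d, h, w = x.shape
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        od, oh, ow = win.shape[2:5]
        flat = win.reshape(n, c, od, oh, ow, k**3)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        out = np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        n, c, d, h, w = self._in_shape
        od, oh, ow = dy.shape[2:]
        kz, rem = np.divmod(self._argmax, k * k)
        ky, kx = np.divmod(rem, k)
        oz = (np.arange(od) * s)[:, None, None]
        oy = (np.arange(oh) * s)[None, :, None]
        ox = (np.arange(ow) * s)[None, None, :]
        iz = oz + kz
        iy = oy + ky
        ix = ox + kx
        flat_idx = (iz * h * w + iy * w + ix).reshape(n, c, -1)
        dx = np.zeros((n, c, d * h * w), dtype=np.float32)
        dyf = dy.reshape(n, c, -1)
        for i in range(n):
            for j in range(c):
                np.add.at(dx[i, j], flat_idx[i, j], dyf[i, j])
        return dx.reshape(n, c, d, h, w)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 init: str = "zero"):
        if init == "zero" or rng is None:
            self.w = np.zeros((n_in, n_out), dtype=np.float32)
        elif init == "xavier":
            limit = np.sqrt(6.0 / (n_in + n_out))
            self.w = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float32)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
            if dy is None:
                break

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
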