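"""Backprop-capable layers on float32 NCHW arrays."""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "ConvTranspose2x2", "MaxPool2", "ReLU",
           "Linear", "GlobalAvgPool", "sigmoid", "softmax"]


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


class Conv2d:
    """3x3 (or kxk) same-padding convolution, stride 1, He-initialised."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32), "conv.W")
        self.b = Param(np.zeros(cout, dtype=np.float32), "conv.b")
        self.k = k
        self.pad = k // 2
        self._xp = None

    def params(self):
        return [self.W, self.b]

    def _cols(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        n, c = xp.shape[0], xp.shape[1]
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * self.k * self.k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._in_shape = x.shape
        cols = self._cols(xp, h, w)
        self._cols_cache = cols
        wm = self.W.value.reshape(self.W.value.shape[0], -1)
        y = cols @ wm.T + self.b.value
        return np.ascontiguousarray(y.reshape(n, h, w, -1).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        cout = self.W.value.shape[0]
        p, k = self.pad, self.k
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.W.grad += (dyf.T @ self._cols_cache).reshape(self.W.value.shape)
        self.b.grad += dyf.sum(axis=0)
        self._cols_cache = None
        # dx = same-padded correlation of dy with the 180deg-rotated kernel
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p))) if p else dy
        cols2 = self._cols(dyp, h, w)
        w_rot = self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(c, -1)
        dx = cols2 @ w_rot.T
        return np.ascontiguousarray(dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))


class ConvTranspose2x2:
    """2x up-convolution (kernel 2, stride 2) used in the U-Net decoder."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * 4))
        self.W = Param(rng.normal(0.0, std, size=(cin, cout, 2, 2)).astype(np.float32), "convT.W")
        self.b = Param(np.zeros(cout, dtype=np.float32), "convT.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        cout = self.W.value.shape[1]
        y = np.einsum("ncij,cfab->nfiajb", x, self.W.value, optimize=True)
        y = y.reshape(n, cout, 2 * h, 2 * w)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        cout = self.W.value.shape[1]
        dyr = dy.reshape(n, cout, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)  # n,f,i,j,a,b
        self.W.grad += np.einsum("ncij,nfijab->cfab", x, dyr, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("nfijab,cfab->ncij", dyr, self.W.value, optimize=True)
        self._x = None
        return dx


class MaxPool2:
    """2x2 max pooling; gradients of ties are split evenly."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = r.max(axis=(3, 5))
        mask = r == y[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        self._weights = mask / counts
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dr = self._weights * dy[:, :, :, None, :, None]
        self._weights = None
        return dr.reshape(self._shape)

    def params(self):
        return []


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._mask
        self._mask = None
        return out

    def params(self):
        return []


class GlobalAvgPool:
    """NCHW -> NC mean over the spatial axes."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)

    def params(self):
        return []


class Linear:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / cin)
        self.W = Param(rng.normal(0.0, std, size=(cout, cin)).astype(np.float32), "linear.W")
        self.b = Param(np.zeros(cout, dtype=np.float32), "linear.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.W.value
        self._x = None
        return dx
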