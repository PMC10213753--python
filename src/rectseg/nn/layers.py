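"""Minimal NumPy neural-network layers with explicit backpropagation.

All layers operate on NHWC float32 tensors (batch, height, width, channels).
Each layer exposes ``forward(x, train)`` and ``backward(dy)`` and keeps its
trainable arrays in ``params`` with matching gradients in ``grads``.
Convolutions are evaluated as sums of shifted channel-matmuls, which lands
the arithmetic in BLAS and keeps a single-CPU training run tractable.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


_OFFSETS3 = [(di, dj) for di in range(3) for dj in range(3)]


class Conv3x3(Layer):
    """3x3 convolution, stride 1, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (9 * c_in))
        self.params = {
            "w": (rng.standard_normal((9, c_in, c_out)) * std).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train):
        b, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._xp, self._shape = xp, (b, h, w)
        wk = self.params["w"]
        yf = np.zeros((b * h * w, self.c_out), dtype=F32)
        for k, (di, dj) in enumerate(_OFFSETS3):
            xs = xp[:, di : di + h, dj : dj + w, :].reshape(-1, self.c_in)
            yf += xs @ wk[k]
        return yf.reshape(b, h, w, self.c_out) + self.params["b"]

    def backward(self, dy):
        b, h, w = self._shape
        xp, wk = self._xp, self.params["w"]
        dyf = np.ascontiguousarray(dy.reshape(-1, self.c_out))
        dw = np.empty_like(wk)
        dxp = np.zeros_like(xp)
        for k, (di, dj) in enumerate(_OFFSETS3):
            xs = xp[:, di : di + h, dj : dj + w, :].reshape(-1, self.c_in)
            dw[k] = xs.T @ dyf
            dxp[:, di : di + h, dj : dj + w, :] += (dyf @ wk[k].T).reshape(b, h, w, self.c_in)
        self.grads = {"w": dw, "b": dyf.sum(0)}
        self._xp = None
        return dxp[:, 1 : h + 1, 1 : w + 1, :]


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / c_in)
        self.params = {
            "w": (rng.standard_normal((c_in, c_out)) * std).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train):
        self._x = x
        b, h, w, _ = x.shape
        y = x.reshape(-1, self.c_in) @ self.params["w"] + self.params["b"]
        return y.reshape(b, h, w, self.c_out)

    def backward(self, dy):
        x = self._x
        b, h, w, _ = x.shape
        dyf = dy.reshape(-1, self.c_out)
        xf = x.reshape(-1, self.c_in)
        self.grads = {"w": xf.T @ dyf, "b": dyf.sum(0)}
        self._x = None
        return (dyf @ self.params["w"].T).reshape(b, h, w, self.c_in)


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (doubles H and W)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / c_in)
        self.params = {
            "w": (rng.standard_normal((c_in, 4 * c_out)) * std).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train):
        self._x = x
        b, h, w, _ = x.shape
        y = x.reshape(-1, self.c_in) @ self.params["w"]
        y = y.reshape(b, h, w, 2, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(y.reshape(b, 2 * h, 2 * w, self.c_out)) + self.params["b"]

    def backward(self, dy):
        x = self._x
        b, h, w, _ = x.shape
        d = dy.reshape(b, h, 2, w, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        d = np.ascontiguousarray(d.reshape(-1, 4 * self.c_out))
        xf = x.reshape(-1, self.c_in)
        self.grads = {
            "w": xf.T @ d,
            "b": dy.reshape(-1, self.c_out).sum(0),
        }
        self._x = None
        return (d @ self.params["w"].T).reshape(b, h, w, self.c_in)


class BatchNorm(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(c, dtype=F32), "beta": np.zeros(c, dtype=F32)}
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat.astype(F32), inv.astype(F32), train)
        return self.params["gamma"] * self._cache[0] + self.params["beta"]

    def backward(self, dy):
        xhat, inv, train = self._cache
        self.grads = {
            "gamma": (dy * xhat).sum(axis=(0, 1, 2)),
            "beta": dy.sum(axis=(0, 1, 2)),
        }
        dxhat = dy * self.params["gamma"]
        if not train:
            return dxhat * inv
        n = float(np.prod(xhat.shape[:3]))
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        dx = (dxhat - s1 / n - xhat * (s2 / n)) * inv
        self._cache = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        out = dy * self._mask
        self._mask = None
        return out


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool2(Layer):
    """2x2 max pooling with stride 2."""

    def forward(self, x, train):
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = np.ascontiguousarray(xr.reshape(b, h // 2, w // 2, c, 4))
        self._idx = xr.argmax(-1)
        self._shape = (b, h, w, c)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b, h, w, c = self._shape
        scat = np.zeros((b, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(scat, self._idx[..., None], dy[..., None], axis=-1)
        scat = scat.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._idx = None
        return np.ascontiguousarray(scat.reshape(b, h, w, c))
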