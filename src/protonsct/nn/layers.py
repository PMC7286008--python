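"""Layers with explicit forward/backward passes on (N, C, H, W) arrays."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Conv2d", "ConvTranspose2d", "MaxPool2d", "BatchNorm2d",
    "ReLU", "LeakyReLU", "Sigmoid", "Dropout", "Flatten", "Dense", "Sequential",
]


class Param:
    """A weight array with its accumulated gradient."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float64)
        self.g = np.zeros_like(self.v)

    def zero_grad(self) -> None:
        self.g[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """k x k convolution, arbitrary stride, symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError(f"kernel size must be odd, got {k}")
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = (k // 2) if pad is None else pad
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(he_init(rng, (c_out, c_in, k, k), c_in * k * k))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        out = cols @ self.W.v.reshape(self.c_out, -1).T + self.b.v
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.W.g += (dyf.T @ cols).reshape(self.W.v.shape)
        self.b.g += dyf.sum(axis=0)
        dcols = (dyf @ self.W.v.reshape(self.c_out, -1)).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (n, c, ho, wo, k, k)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += dcols[:, :, :, :, ki, kj]
        return dxp[:, :, p:p + h, p:p + w]


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (exact x2 upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(he_init(rng, (c_in, c_out, 2, 2), c_in))
        self.b = Param(np.zeros(c_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        self._x = x
        y6 = np.einsum("ncij,codh->noidjh", x, self.W.v)
        y = y6.reshape(n, self.c_out, 2 * h, 2 * w) + self.b.v[None, :, None, None]
        return y

    def backward(self, dy):
        n, co, h2, w2 = dy.shape
        dy6 = dy.reshape(n, co, h2 // 2, 2, w2 // 2, 2)
        self.W.g += np.einsum("ncij,noidjh->codh", self._x, dy6)
        self.b.g += dy.sum(axis=(0, 2, 3))
        return np.einsum("noidjh,codh->ncij", dy6, self.W.v)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._xshape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._xshape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]

    def backward(self, dy):
        xhat, inv, training, shape = self._cache
        self.gamma.g += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.g += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.v[None, :, None, None]
        if not training:
            return dxhat * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        t1 = dxhat - dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
        t2 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return inv[None, :, None, None] * (t1 - t2)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Layer):
    """max(x, alpha*x); keeps a nonzero gradient on inactive units, which
    matters for narrow discriminators whose early layers otherwise die."""

    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return dy * np.where(self._mask, 1.0, self.alpha)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(he_init(rng, (d_in, d_out), d_in))
        self.b = Param(np.zeros(d_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, dy):
        self.W.g += self._x.T @ dy
        self.b.g += dy.sum(axis=0)
        return dy @ self.W.v.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
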