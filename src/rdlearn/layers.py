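"""Neural-network layer primitives with explicit forward/backward passes.

Each layer caches what its backward pass needs during ``forward`` and
exposes trainable arrays in ``params`` with matching ``grads``.  Weight
initialisation is fan-in-scaled uniform, drawn from the generator passed to
``init`` so that model construction is deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from .convops import col2im, im2col, out_size, pad_input

__all__ = [
    "Layer",
    "Dense",
    "Conv2D",
    "MaxPool2D",
    "AvgPool2D",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "Flatten",
    "Softmax",
]


class Layer:
    """Base class; stateless layers leave ``params`` empty."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover - trivial
        pass

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Dense(Layer):
    def __init__(self, name: str, n_in: int, n_out: int):
        super().__init__(name)
        self.n_in, self.n_out = n_in, n_out
        self.params = {"W": np.zeros((n_in, n_out)), "b": np.zeros(n_out)}
        self.zero_grads()

    def init(self, rng):
        self.params["W"] = _fan_in_uniform(rng, (self.n_in, self.n_out), self.n_in)
        self.params["b"] = _fan_in_uniform(rng, (self.n_out,), self.n_in)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Conv2D(Layer):
    def __init__(self, name, in_ch, out_ch, kernel, stride=1, pad=0):
        super().__init__(name)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, pad
        fan = in_ch * kernel * kernel
        self.params = {
            "W": np.zeros((out_ch, fan)),
            "b": np.zeros(out_ch),
        }
        self.zero_grads()

    def init(self, rng):
        fan = self.in_ch * self.k * self.k
        self.params["W"] = _fan_in_uniform(rng, (self.out_ch, fan), fan)
        self.params["b"] = _fan_in_uniform(rng, (self.out_ch,), fan)

    def out_shape(self, in_shape):
        c, h, w = in_shape
        oh = out_size(h, self.k, self.stride, 2 * self.pad)
        ow = out_size(w, self.k, self.stride, 2 * self.pad)
        return (self.out_ch, oh, ow)

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        oh = out_size(h, self.k, self.stride, 2 * self.pad)
        ow = out_size(w, self.k, self.stride, 2 * self.pad)
        xp = pad_input(x, self.pad, self.pad, self.pad, self.pad)
        cols = im2col(xp, self.k, self.k, self.stride, oh, ow)
        cols = cols.reshape(n, c * self.k * self.k, oh * ow)
        out = np.matmul(self.params["W"][None], cols) + self.params["b"][None, :, None]
        self._cache = (cols, xp.shape, (h, w), (oh, ow))
        return out.reshape(n, self.out_ch, oh, ow)

    def backward(self, dout):
        cols, padded_shape, (h, w), (oh, ow) = self._cache
        n = dout.shape[0]
        dflat = dout.reshape(n, self.out_ch, oh * ow)
        self.grads["W"] = np.einsum("nol,nkl->ok", dflat, cols)
        self.grads["b"] = dflat.sum(axis=(0, 2))
        dcols = np.matmul(self.params["W"].T[None], dflat)
        dxp = col2im(dcols, padded_shape, self.k, self.k, self.stride, oh, ow)
        if self.pad:
            dxp = dxp[:, :, self.pad : self.pad + h, self.pad : self.pad + w]
        return dxp


class _Pool2D(Layer):
    def __init__(self, name, kernel, stride=None, ceil_mode=False):
        super().__init__(name)
        self.k = kernel
        self.stride = stride if stride is not None else kernel
        self.ceil_mode = ceil_mode

    def _geometry(self, h, w):
        k = self.k
        oh = out_size(h, k, self.stride, 0, self.ceil_mode)
        ow = out_size(w, k, self.stride, 0, self.ceil_mode)
        ph = max(0, (oh - 1) * self.stride + k - h)
        pw = max(0, (ow - 1) * self.stride + k - w)
        return k, oh, ow, ph, pw

    def out_shape(self, in_shape):
        c, h, w = in_shape
        _, oh, ow, _, _ = self._geometry(h, w)
        return (c, oh, ow)


class MaxPool2D(_Pool2D):
    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        k, oh, ow, ph, pw = self._geometry(h, w)
        xp = pad_input(x, 0, ph, 0, pw, value=-np.inf)
        cols = im2col(xp, k, k, self.stride, oh, ow)  # (N, C, k*k, L)
        arg = cols.argmax(axis=2)
        out = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (arg, xp.shape, (h, w), k, oh, ow)
        return out.reshape(n, c, oh, ow)

    def backward(self, dout):
        arg, padded_shape, (h, w), k, oh, ow = self._cache
        n, c = dout.shape[:2]
        dcols = np.zeros((n, c, k * k, oh * ow), dtype=dout.dtype)
        np.put_along_axis(
            dcols, arg[:, :, None, :], dout.reshape(n, c, 1, oh * ow), axis=2
        )
        dxp = col2im(dcols.reshape(n, c * k * k, oh * ow), padded_shape, k, k,
                     self.stride, oh, ow)
        return dxp[:, :, :h, :w]


class AvgPool2D(_Pool2D):
    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        k, oh, ow, ph, pw = self._geometry(h, w)
        xp = pad_input(x, 0, ph, 0, pw, value=0.0)
        cols = im2col(xp, k, k, self.stride, oh, ow)
        out = cols.mean(axis=2)
        self._cache = (xp.shape, (h, w), k, oh, ow)
        return out.reshape(n, c, oh, ow)

    def backward(self, dout):
        padded_shape, (h, w), k, oh, ow = self._cache
        n, c = dout.shape[:2]
        dcols = np.broadcast_to(
            dout.reshape(n, c, 1, oh * ow) / (k * k), (n, c, k * k, oh * ow)
        )
        dxp = col2im(
            np.ascontiguousarray(dcols).reshape(n, c * k * k, oh * ow),
            padded_shape, k, k, self.stride, oh, ow,
        )
        return dxp[:, :, :h, :w]


class BatchNorm(Layer):
    """Batch normalisation over the batch (and spatial dims for 4-D input),
    one scale/shift pair per feature channel."""

    def __init__(self, name, n_features, eps=1e-5, momentum=0.9):
        super().__init__(name)
        self.n_features = n_features
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.buffers = {
            "running_mean": np.zeros(n_features),
            "running_var": np.ones(n_features),
        }
        self.zero_grads()

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _expand(self, v, ndim):
        return v if ndim == 2 else v[:, None, None]

    def forward(self, x, train=False, rng=None):
        axes = self._axes(x)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"] = m * self.buffers["running_mean"] + (1 - m) * mu
            self.buffers["running_var"] = m * self.buffers["running_var"] + (1 - m) * var
        else:
            mu = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        e = lambda v: self._expand(v, x.ndim)
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - e(mu)) * e(ivstd)
        self._cache = (xhat, ivstd, axes, train, x.ndim)
        return e(self.params["gamma"]) * xhat + e(self.params["beta"])

    def backward(self, dout):
        xhat, ivstd, axes, train, ndim = self._cache
        e = lambda v: self._expand(v, ndim)
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * e(self.params["gamma"])
        if not train:
            return dxhat * e(ivstd)
        m = dout.size / dout.shape[1] if ndim == 4 else dout.shape[0]
        mean_d = dxhat.mean(axis=axes)
        mean_dx = (dxhat * xhat).mean(axis=axes)
        return e(ivstd) * (dxhat - e(mean_d) - xhat * e(mean_dx))


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, name, p):
        super().__init__(name)
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode requires a generator")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Softmax(Layer):
    """Row-wise normalised exponentiation: outputs can be read as class
    probabilities."""

    def forward(self, x, train=False, rng=None):
        z = x - x.max(axis=1, keepdims=True)
        ez = np.exp(z)
        self._p = ez / ez.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, dout):
        p = self._p
        return p * (dout - (dout * p).sum(axis=1, keepdims=True))
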