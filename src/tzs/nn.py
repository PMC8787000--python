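"""Minimal 3D convolutional network layers in numpy with manual backprop.

Implements exactly what the patch classifier needs: 3D convolution
(stride 1, "same" padding), batch normalization, ReLU, max pooling, dense
layers, inverted dropout, and Adam. Tensors are ``(N, C, D, H, W)``.
Everything is driven by explicit ``numpy.random.Generator`` streams so
training is reproducible.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "Conv3D",
    "BatchNorm3D",
    "ReLU",
    "MaxPool3D",
    "Flatten",
    "Dense",
    "Dropout",
    "Adam",
]


class Layer:
    """Base class: layers expose ``params``/``grads`` dicts for the optimizer."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# Compiled inner loops: a 3x3x3 stride-1 "same" convolution dominates the
# training cost, so its forward pass and both gradient passes run as
# cache-compiled numba kernels instead of materializing im2col windows.


@njit(cache=True, fastmath=True)
def _conv3d_forward(xp, w, y):  # pragma: no cover - exercised via Conv3D
    n_batch, n_in = xp.shape[0], xp.shape[1]
    n_out = w.shape[0]
    d, h, wd = y.shape[2], y.shape[3], y.shape[4]
    for n in range(n_batch):
        for o in range(n_out):
            for c in range(n_in):
                for i in range(3):
                    for j in range(3):
                        for k in range(3):
                            wv = w[o, c, i, j, k]
                            for z in range(d):
                                for yy in range(h):
                                    for xx in range(wd):
                                        y[n, o, z, yy, xx] += wv * xp[n, c, z + i, yy + j, xx + k]


@njit(cache=True, fastmath=True)
def _conv3d_grad_w(xp, dy, dw):  # pragma: no cover
    n_batch, n_in = xp.shape[0], xp.shape[1]
    n_out = dy.shape[1]
    d, h, wd = dy.shape[2], dy.shape[3], dy.shape[4]
    for o in range(n_out):
        for c in range(n_in):
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        acc = 0.0
                        for n in range(n_batch):
                            for z in range(d):
                                for yy in range(h):
                                    for xx in range(wd):
                                        acc += dy[n, o, z, yy, xx] * xp[n, c, z + i, yy + j, xx + k]
                        dw[o, c, i, j, k] = acc


@njit(cache=True, fastmath=True)
def _conv3d_grad_x(dyp, w, dx):  # pragma: no cover
    n_batch, n_out = dyp.shape[0], dyp.shape[1]
    n_in = w.shape[1]
    d, h, wd = dx.shape[2], dx.shape[3], dx.shape[4]
    for n in range(n_batch):
        for c in range(n_in):
            for o in range(n_out):
                for i in range(3):
                    for j in range(3):
                        for k in range(3):
                            wv = w[o, c, 2 - i, 2 - j, 2 - k]
                            for z in range(d):
                                for yy in range(h):
                                    for xx in range(wd):
                                        dx[n, c, z, yy, xx] += wv * dyp[n, o, z + i, yy + j, xx + k]


class Conv3D(Layer):
    """3x3x3 convolution, stride 1, same padding, He-initialized."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel != 3:
            raise ValueError("only kernel size 3 is supported")
        self.kernel = kernel
        fan_in = in_channels * kernel ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel, kernel, kernel))
        self.params = {"w": w.astype(np.float32), "b": np.zeros(out_channels, dtype=np.float32)}
        self._xp = None

    def forward(self, x, train, rng):
        x = np.ascontiguousarray(x, dtype=np.float32)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        self._xp = xp if train else None
        n, _, d, h, wd = x.shape
        y = np.zeros((n, self.params["w"].shape[0], d, h, wd), dtype=np.float32)
        _conv3d_forward(xp, self.params["w"], y)
        return y + self.params["b"][None, :, None, None, None]

    def backward(self, dy):
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        dw = np.zeros_like(self.params["w"])
        _conv3d_grad_w(self._xp, dy, dw)
        self.grads["w"] = dw
        self.grads["b"] = dy.sum(axis=(0, 2, 3, 4))
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        dx = np.zeros_like(self._xp[:, : self.params["w"].shape[1], 1:-1, 1:-1, 1:-1])
        _conv3d_grad_x(dyp, self.params["w"], dx)
        self._xp = None
        return dx


class BatchNorm3D(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train, rng):
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes, dtype=np.float32)
            var = x.var(axis=axes, dtype=np.float32)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean.reshape(shape)) / std.reshape(shape)
        if train:
            self._cache = (xhat, std)
        return self.params["gamma"].reshape(shape) * xhat + self.params["beta"].reshape(shape)

    def backward(self, dy):
        xhat, std = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        m = dy.size / dy.shape[1]
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"].reshape(shape)
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
        ) / std.reshape(shape)
        return dx


class ReLU(Layer):
    def forward(self, x, train, rng):
        mask = x > 0
        self._mask = mask if train else None
        return x * mask

    def backward(self, dy):
        dy = dy * self._mask
        self._mask = None
        return dy


class MaxPool3D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool
        self._cache = None

    def forward(self, x, train, rng):
        p = self.pool
        n, c, d, h, w = x.shape
        if d % p or h % p or w % p:
            raise ValueError("spatial size not divisible by pool size")
        xr = x.reshape(n, c, d // p, p, h // p, p, w // p, p)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // p, h // p, w // p, p ** 3)
        arg = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, x.shape)
        return y

    def backward(self, dy):
        arg, shape = self._cache
        self._cache = None
        p = self.pool
        n, c, d, h, w = shape
        dxr = np.zeros((n, c, d // p, h // p, w // p, p ** 3), dtype=dy.dtype)
        np.put_along_axis(dxr, arg[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, d // p, h // p, w // p, p, p, p)
        dxr = dxr.transpose(0, 1, 2, 5, 3, 6, 4, 7)
        return dxr.reshape(shape)


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        self.params = {"w": w.astype(np.float32), "b": np.zeros(out_features, dtype=np.float32)}
        self._x = None

    def forward(self, x, train, rng):
        self._x = x if train else None
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        self.grads["w"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["w"].T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dy = dy * self._mask
        self._mask = None
        return dy


class Adam:
    def __init__(self, layers, learning_rate: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = self.beta1 * self.m[i][k] + (1 - self.beta1) * g
                self.v[i][k] = self.beta2 * self.v[i][k] + (1 - self.beta2) * g * g
                mhat = self.m[i][k] / b1t
                vhat = self.v[i][k] / b2t
                layer.params[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
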