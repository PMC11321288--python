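"""Minimal CPU neural-network layer library used by the BYOL encoder.

Implements exactly the pieces the self-supervised pipeline needs —
strided 3x3 convolutions (im2col), batch normalisation, ReLU, global
average pooling, linear layers, Adam — each with a hand-written backward
pass so that training and GradCAM gradient routing run on numpy alone.
Parameters and activations are float32; images enter as (N, C, H, W).
"""

from __future__ import annotations

import copy

import numpy as np
from numba import njit

DTYPE = np.float32

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "BatchNorm1d",
    "ReLU",
    "AvgPool2d",
    "GlobalAvgPool",
    "GlobalMaxPool",
    "GlobalAvgMaxPool",
    "Linear",
    "Sequential",
    "Adam",
]


@njit(cache=False)
def _im2col_kernel(x, cols, k, stride):
    n, c, hp, wp = x.shape
    nl, f = cols.shape
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    for ni in range(n):
        for oy in range(oh):
            for ox in range(ow):
                row = (ni * oh + oy) * ow + ox
                for ci in range(c):
                    base = ci * k * k
                    for i in range(k):
                        for j in range(k):
                            cols[row, base + i * k + j] = x[ni, ci, oy * stride + i,
                                                            ox * stride + j]


@njit(cache=False)
def _col2im_kernel(dcols, dx, k, stride):
    n, c, hp, wp = dx.shape
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    for ni in range(n):
        for oy in range(oh):
            for ox in range(ow):
                row = (ni * oh + oy) * ow + ox
                for ci in range(c):
                    base = ci * k * k
                    for i in range(k):
                        for j in range(k):
                            dx[ni, ci, oy * stride + i, ox * stride + j] += \
                                dcols[row, base + i * k + j]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold (N,C,H,W) into (N*L, C*k*k) patch rows ready for BLAS."""
    if pad:
        # reflect padding: zero-padding imprints absolute position at borders
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="reflect")
    x = np.ascontiguousarray(x)
    n, c, h, w = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    cols = np.empty((n * oh * ow, c * k * k), dtype=x.dtype)
    _im2col_kernel(x, cols, k, stride)
    return cols, (n, c, h, w, oh, ow)

def _col2im(dcols: np.ndarray, shape, k: int, stride: int, pad: int):
    n, c, h, w, oh, ow = shape
    dx = np.zeros((n, c, h, w), dtype=dcols.dtype)
    _col2im_kernel(np.ascontiguousarray(dcols), dx, k, stride)
    if pad:
        # fold reflect-padded border gradients back into the interior
        for j in range(pad):
            dx[:, :, 2 * pad - j, :] += dx[:, :, j, :]
            dx[:, :, h - 2 * pad - 1 + j, :] += dx[:, :, h - 1 - j, :]
            dx[:, :, :, 2 * pad - j] += dx[:, :, :, j]
            dx[:, :, :, w - 2 * pad - 1 + j] += dx[:, :, :, w - 1 - j]
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Layer:
    """Base class; layers cache forward state for the following backward."""

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def buffers(self) -> dict:
        return {}

    def state_arrays(self) -> dict:
        out = dict(self.params())
        out.update(self.buffers())
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, pad: int = 1, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.k, self.stride, self.pad = k, stride, pad
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.gW, "b": self.gb}

    def forward(self, x, train):
        cols, shape = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._shape = cols, shape
        n, _, _, _, oh, ow = shape
        y = cols @ self.W + self.b              # (N*L, cout)
        return y.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, co, oh, ow = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * oh * ow, co)
        self.gW[...] = self._cols.T @ dyf
        self.gb[...] = dyf.sum(axis=0)
        dcols = dyf @ self.W.T
        return _col2im(dcols, self._shape, self.k, self.stride, self.pad)


class _BatchNormBase(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.ggamma = np.zeros(c)
        self.gbeta = np.zeros(c)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.ggamma, "beta": self.gbeta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    _axes: tuple

    def _shape_c(self, v, x):
        sh = [1] * x.ndim
        sh[1] = -1
        return v.reshape(sh)

    def forward(self, x, train):
        self._train = train
        if train:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            self.running_mean[...] = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var[...] = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape_c(mean, x)) * self._shape_c(invstd, x)
        self._xhat, self._invstd = xhat, invstd
        return self._shape_c(self.gamma, x) * xhat + self._shape_c(self.beta, x)

    def backward(self, dy):
        xhat, invstd = self._xhat, self._invstd
        self.ggamma[...] = (dy * xhat).sum(axis=self._axes)
        self.gbeta[...] = dy.sum(axis=self._axes)
        g = self._shape_c(self.gamma * invstd, dy)
        if not self._train:
            return dy * g
        m = dy.size / dy.shape[1]
        dxhat = dy * self._shape_c(self.gamma, dy)
        t1 = dxhat - self._shape_c(dxhat.sum(axis=self._axes) / m, dy)
        t2 = xhat * self._shape_c((dxhat * xhat).sum(axis=self._axes) / m, dy)
        return (t1 - t2) * self._shape_c(invstd, dy)


class BatchNorm2d(_BatchNormBase):
    _axes = (0, 2, 3)


class BatchNorm1d(_BatchNormBase):
    _axes = (0,)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool2d(Layer):
    """Non-overlapping s x s average pooling; front-end speckle suppression."""

    def __init__(self, s: int = 2):
        self.s = s

    def forward(self, x, train):
        n, c, h, w = x.shape
        s = self.s
        self._shape = x.shape
        return x.reshape(n, c, h // s, s, w // s, s).mean(axis=(3, 5))

    def backward(self, dy):
        n, c, h, w = self._shape
        s = self.s
        up = np.broadcast_to(dy[:, :, :, None, :, None],
                             (n, c, h // s, s, w // s, s))
        return up.reshape(n, c, h, w) / (s * s)


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean; the encoder's feature readout."""

    def forward(self, x, train):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        h, w = self._hw
        return np.broadcast_to(dy[:, :, None, None], dy.shape + (h, w)).copy() / (h * w)


class GlobalMaxPool(Layer):
    """(N,C,H,W) -> (N,C) spatial max; translation-invariant readout."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        self._shape = x.shape
        flat = x.reshape(n, c, h * w)
        self._argmax = flat.argmax(axis=2)
        return flat.max(axis=2)

    def backward(self, dy):
        n, c, h, w = self._shape
        dx = np.zeros((n, c, h * w), dtype=dy.dtype)
        ii, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        dx[ii, cc, self._argmax] = dy
        return dx.reshape(n, c, h, w)


class GlobalAvgMaxPool(Layer):
    """(N,C,H,W) -> (N,2C): spatial mean concatenated with spatial max.

    The max half preserves small, localized high-activation responses
    (focal lesions) that plain averaging washes out.
    """

    def forward(self, x, train):
        n, c, h, w = x.shape
        self._shape = x.shape
        flat = x.reshape(n, c, h * w)
        self._argmax = flat.argmax(axis=2)
        return np.concatenate([flat.mean(axis=2), flat.max(axis=2)], axis=1)

    def backward(self, dy):
        n, c, h, w = self._shape
        davg, dmax = dy[:, :c], dy[:, c:]
        dx = np.broadcast_to(davg[:, :, None, None] / (h * w),
                             (n, c, h, w)).copy()
        flat = dx.reshape(n, c, h * w)
        ii, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        flat[ii, cc, self._argmax] += dmax
        return flat.reshape(n, c, h, w)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.gW, "b": self.gb}

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.gW[...] = self._x.T @ dy
        self.gb[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def forward_collect(self, x, train=False):
        """Forward pass that also returns every intermediate output (GradCAM)."""
        outs = []
        for layer in self.layers:
            x = layer.forward(x, train)
            outs.append(x)
        return x, outs

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def state_arrays(self) -> dict:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.state_arrays().items():
                out[f"{i}.{name}"] = arr
        return out

    def load_state_arrays(self, arrays: dict):
        own = self.state_arrays()
        if set(own) != set(arrays):
            raise ValueError("state key mismatch")
        for key, arr in arrays.items():
            if own[key].shape != np.shape(arr):
                raise ValueError(f"shape mismatch for {key}")
            own[key][...] = arr

    def param_items(self):
        for i, layer in enumerate(self.layers):
            grads = layer.grads()
            for name, arr in layer.params().items():
                yield f"{i}.{name}", arr, grads[name]

    def clone(self) -> "Sequential":
        return copy.deepcopy(self)


class Adam:
    """Adam with additive L2 weight decay over one or more Sequential modules."""

    def __init__(self, modules, lr=5e-4, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.modules = list(modules)
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self):
        self.t += 1
        for mi, mod in enumerate(self.modules):
            for name, p, g in mod.param_items():
                key = (mi, name)
                g = g + self.wd * p
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m[...] = self.b1 * m + (1 - self.b1) * g
                v[...] = self.b2 * v + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
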