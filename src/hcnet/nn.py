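"""Minimal CPU neural-network layers with explicit backpropagation.

Everything is plain NumPy.  Convolutions are evaluated as a sum of batched
GEMMs, one per kernel offset: for a kernel position ``k`` the padded input is
sliced with the layer stride and multiplied by the ``C_in x C_out`` weight
slab ``W[..., k]``.  This keeps memory proportional to the activations (no
im2col buffer) while every FLOP goes through BLAS.

Layers follow a two-phase protocol: ``forward(x, training=...)`` caches what
the gradient needs, ``backward(grad)`` accumulates parameter gradients and
returns the gradient with respect to the input.  There is no autograd graph;
the network that uses these layers wires the reverse pass explicitly.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Conv",
    "ConvTranspose",
    "BatchNorm",
    "ReLU",
    "MaxPool",
    "Adam",
    "softmax",
]


class Parameter:
    """A trainable array together with its accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name or 'unnamed'}, shape={self.value.shape})"


class Module:
    """Base class: a layer exposing its parameters."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def _tuplify(v, rank: int) -> tuple[int, ...]:
    if np.isscalar(v):
        return (int(v),) * rank
    t = tuple(int(x) for x in v)
    if len(t) != rank:
        raise ValueError(f"expected {rank} entries, got {t}")
    return t


def _pad(x: np.ndarray, pad: tuple[int, ...]) -> np.ndarray:
    if not any(pad):
        return x
    width = [(0, 0), (0, 0)] + [(p, p) for p in pad]
    return np.pad(x, width)


def _out_spatial(in_sp, kernel, stride, pad):
    return tuple((s + 2 * p - k) // st + 1 for s, k, st, p in zip(in_sp, kernel, stride, pad))


def _offset_slices(k_off, stride, out_sp):
    return tuple(
        slice(k, k + st * o, st) for k, st, o in zip(k_off, stride, out_sp)
    )


def conv_forward(x, w, stride, pad):
    """N-d cross-correlation. x: (N,Ci,*S); w: (Co,Ci,*K) -> (N,Co,*O)."""
    rank = x.ndim - 2
    kernel = w.shape[2:]
    out_sp = _out_spatial(x.shape[2:], kernel, stride, pad)
    xp = _pad(x, pad)
    n = x.shape[0]
    co = w.shape[0]
    out = np.zeros((n, co, int(np.prod(out_sp))), dtype=x.dtype)
    for k_off in itertools.product(*(range(k) for k in kernel)):
        xs = xp[(slice(None), slice(None)) + _offset_slices(k_off, stride, out_sp)]
        xs = np.ascontiguousarray(xs).reshape(n, x.shape[1], -1)
        wk = w[(slice(None), slice(None)) + k_off]  # (Co, Ci)
        out += np.matmul(wk, xs)
    return out.reshape((n, co) + out_sp)


def conv_input_grad(g, w, stride, pad, in_spatial):
    """Gradient of conv_forward w.r.t. its input (also transpose-conv forward).

    g: (N,Co,*O); w: (Co,Ci,*K) -> (N,Ci,*in_spatial)
    """
    rank = g.ndim - 2
    kernel = w.shape[2:]
    out_sp = g.shape[2:]
    n, co = g.shape[:2]
    ci = w.shape[1]
    padded_sp = tuple(s + 2 * p for s, p in zip(in_spatial, pad))
    dxp = np.zeros((n, ci) + padded_sp, dtype=g.dtype)
    g2 = g.reshape(n, co, -1)
    for k_off in itertools.product(*(range(k) for k in kernel)):
        wk = w[(slice(None), slice(None)) + k_off]  # (Co, Ci)
        contrib = np.matmul(wk.T, g2).reshape((n, ci) + out_sp)
        dxp[(slice(None), slice(None)) + _offset_slices(k_off, stride, out_sp)] += contrib
    if any(pad):
        core = tuple(slice(p, p + s) for p, s in zip(pad, in_spatial))
        dxp = dxp[(slice(None), slice(None)) + core]
    return dxp


def conv_weight_grad(x, g, stride, pad, kernel):
    """Gradient of conv_forward w.r.t. the weight.

    x: (N,Ci,*S); g: (N,Co,*O) -> (Co,Ci,*kernel)
    """
    out_sp = g.shape[2:]
    n, co = g.shape[:2]
    ci = x.shape[1]
    xp = _pad(x, pad)
    perm = (1, 0) + tuple(range(2, g.ndim))
    g2 = np.ascontiguousarray(g.transpose(perm)).reshape(co, -1)  # (Co, N*P)
    dw = np.zeros((co, ci) + tuple(kernel), dtype=x.dtype)
    for k_off in itertools.product(*(range(k) for k in kernel)):
        xs = xp[(slice(None), slice(None)) + _offset_slices(k_off, stride, out_sp)]
        xs = np.ascontiguousarray(xs.transpose(perm)).reshape(ci, -1)
        dw[(slice(None), slice(None)) + k_off] = g2 @ xs.T
    return dw


class Conv(Module):
    """N-dimensional convolution (cross-correlation) with bias."""

    def __init__(self, in_channels, out_channels, kernel, stride=1, pad=0,
                 rank=2, rng=None, dtype=np.float32, name=""):
        self.rank = rank
        self.kernel = _tuplify(kernel, rank)
        self.stride = _tuplify(stride, rank)
        self.pad = _tuplify(pad, rank)
        fan_in = in_channels * int(np.prod(self.kernel))
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, (out_channels, in_channels) + self.kernel)
        self.w = Parameter(w.astype(dtype), f"{name}.w")
        self.b = Parameter(np.zeros(out_channels, dtype=dtype), f"{name}.b")
        self._x = None

    def forward(self, x, training=False):
        if training:
            self._x = x
        y = conv_forward(x, self.w.value, self.stride, self.pad)
        y += self.b.value.reshape((1, -1) + (1,) * self.rank)
        return y

    def backward(self, grad):
        x = self._x
        self.w.grad += conv_weight_grad(x, grad, self.stride, self.pad, self.kernel)
        self.b.grad += grad.sum(axis=(0,) + tuple(range(2, grad.ndim)))
        dx = conv_input_grad(grad, self.w.value, self.stride, self.pad, x.shape[2:])
        self._x = None
        return dx


class ConvTranspose(Module):
    """N-dimensional transposed convolution with bias.

    Weight layout is (in_channels, out_channels, *kernel); the forward pass is
    the adjoint of a strided convolution, so output spatial size is
    ``stride*(in-1) + kernel - 2*pad``.
    """

    def __init__(self, in_channels, out_channels, kernel, stride=2, pad=1,
                 rank=2, rng=None, dtype=np.float32, name=""):
        self.rank = rank
        self.kernel = _tuplify(kernel, rank)
        self.stride = _tuplify(stride, rank)
        self.pad = _tuplify(pad, rank)
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * int(np.prod(self.kernel)) // int(np.prod(self.stride))
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, (in_channels, out_channels) + self.kernel)
        self.w = Parameter(w.astype(dtype), f"{name}.w")
        self.b = Parameter(np.zeros(out_channels, dtype=dtype), f"{name}.b")
        self._x = None

    def out_spatial(self, in_sp):
        return tuple(
            st * (s - 1) + k - 2 * p
            for s, k, st, p in zip(in_sp, self.kernel, self.stride, self.pad)
        )

    def forward(self, x, training=False):
        if training:
            self._x = x
        y = conv_input_grad(x, self.w.value, self.stride, self.pad,
                            self.out_spatial(x.shape[2:]))
        y += self.b.value.reshape((1, -1) + (1,) * self.rank)
        return y

    def backward(self, grad):
        x = self._x
        # forward was the adjoint of conv(.; w): input grad is the conv itself
        dx = conv_forward(grad, self.w.value, self.stride, self.pad)
        self.w.grad += conv_weight_grad(grad, x, self.stride, self.pad, self.kernel)
        self.b.grad += grad.sum(axis=(0,) + tuple(range(2, grad.ndim)))
        self._x = None
        return dx


class BatchNorm(Module):
    """Batch normalization over the channel axis (axis 1) of a 4-d/5-d tensor."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32, name=""):
        self.gamma = Parameter(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, training=False):
        axes = (0,) + tuple(range(2, x.ndim))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            n = x.size // x.shape[1]
            self.running_mean = (1 - m) * self.running_mean + m * mean
            # running variance uses the unbiased estimator, batch pass the biased one
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            mean = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        bs = self._bshape(x.ndim)
        xhat = (x - mean.reshape(bs)) * invstd.reshape(bs)
        if training:
            self._cache = (xhat, invstd)
        return self.gamma.value.reshape(bs) * xhat + self.beta.value.reshape(bs)

    def backward(self, grad):
        xhat, invstd = self._cache
        self._cache = None
        axes = (0,) + tuple(range(2, grad.ndim))
        bs = self._bshape(grad.ndim)
        n = grad.size // grad.shape[1]
        dgamma = (grad * xhat).sum(axis=axes)
        dbeta = grad.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value.reshape(bs)
        dx = (g * invstd.reshape(bs) / n) * (
            n * grad - dbeta.reshape(bs) - xhat * dgamma.reshape(bs)
        )
        return dx


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool(Module):
    """Max pooling with window == stride and evenly divisible spatial dims."""

    def __init__(self, window: Sequence[int]):
        self.window = tuple(int(w) for w in window)
        self._cache = None

    def forward(self, x, training=False):
        win = self.window
        sp = x.shape[2:]
        if len(sp) != len(win):
            raise ValueError("pooling window rank mismatch")
        for s, w in zip(sp, win):
            if s % w:
                raise ValueError(f"spatial dim {s} not divisible by window {w}")
        out_sp = tuple(s // w for s, w in zip(sp, win))
        split = []
        for o, w in zip(out_sp, win):
            split += [o, w]
        xr = x.reshape(x.shape[:2] + tuple(split))
        # move the window axes to the end and flatten them
        win_axes = tuple(3 + 2 * i for i in range(len(win)))
        keep_axes = tuple(2 + 2 * i for i in range(len(win)))
        xr = np.moveaxis(xr, win_axes, tuple(range(-len(win), 0)))
        flat = np.ascontiguousarray(xr).reshape(x.shape[:2] + out_sp + (-1,))
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape, out_sp)
        return out

    def backward(self, grad):
        idx, in_shape, out_sp = self._cache
        self._cache = None
        win = self.window
        flat = np.zeros(in_shape[:2] + out_sp + (int(np.prod(win)),), dtype=grad.dtype)
        np.put_along_axis(flat, idx[..., None], grad[..., None], axis=-1)
        xr = flat.reshape(in_shape[:2] + out_sp + win)
        win_axes = tuple(range(-len(win), 0))
        dest_axes = tuple(3 + 2 * i for i in range(len(win)))
        xr = np.moveaxis(xr, win_axes, dest_axes)
        return np.ascontiguousarray(xr).reshape(in_shape)


def softmax(x: np.ndarray, axis: int = 1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params: Sequence[Parameter], lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
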