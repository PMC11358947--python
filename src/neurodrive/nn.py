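"""Minimal numpy neural-network engine.

Implements exactly the layers the EEGNet architecture needs — temporal
convolution, full-channel depthwise (spatial) convolution, depthwise +
pointwise (separable) temporal convolution, batch normalisation, ELU,
temporal average pooling, dropout, dense and softmax cross-entropy — with
hand-written backward passes and an Adam optimiser.  Every backward pass
is validated against central finite differences in the test suite.

Tensor convention: activations are (batch, maps, channels, time) float64
("maps" is the filter axis; raw input enters as (B, 1, C, T)).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _same_pad(k: int) -> tuple[int, int]:
    # stride-1 'same' padding; even kernels pad one extra on the right
    return (k - 1) // 2, k // 2


def _twin(x: np.ndarray, k: int, pl: int, pr: int) -> np.ndarray:
    """Sliding windows of length k along the last (time) axis after padding."""
    pad = [(0, 0)] * (x.ndim - 1) + [(pl, pr)]
    return sliding_window_view(np.pad(x, pad), k, axis=-1)


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: subclasses fill ``params``/``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, in_shape: tuple) -> tuple:
        return in_shape


class TemporalConv(Layer):
    """Conv2D with kernel (1, k): mixes input maps, convolves along time."""

    def __init__(self, in_maps: int, out_maps: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k = k
        self.pl, self.pr = _same_pad(k)
        fan_in, fan_out = in_maps * k, out_maps * k
        self.params["W"] = glorot_uniform(rng, (out_maps, in_maps, k), fan_in, fan_out)

    def forward(self, x, training=False):
        self._xwin = _twin(x, self.k, self.pl, self.pr)        # (B,I,C,T,k)
        return np.einsum("bictk,oik->boct", self._xwin, self.params["W"])

    def backward(self, dy):
        self.grads["W"] = np.einsum("bictk,boct->oik", self._xwin, dy)
        wf = self.params["W"][:, :, ::-1]
        dywin = _twin(dy, self.k, self.k - 1 - self.pl, self.k - 1 - self.pr)
        return np.einsum("boctk,oik->bict", dywin, wf)

    def output_shape(self, s):
        return (self.params["W"].shape[0], s[1], s[2])


class DepthwiseSpatialConv(Layer):
    """DepthwiseConv2D with kernel (C, 1): collapses the channel axis,
    expanding each of F1 maps into D spatial filters (F1*D output maps)."""

    def __init__(self, in_maps: int, depth: int, n_channels: int, rng: np.random.Generator):
        super().__init__()
        self.in_maps, self.depth, self.C = in_maps, depth, n_channels
        self.params["W"] = glorot_uniform(
            rng, (in_maps, depth, n_channels), n_channels, depth)

    def forward(self, x, training=False):
        self._x = x                                           # (B,F1,C,T)
        y = np.einsum("bfct,fdc->bfdt", x, self.params["W"])  # (B,F1,D,T)
        B, F, D, T = y.shape
        return y.reshape(B, F * D, 1, T)

    def backward(self, dy):
        B, M, _, T = dy.shape
        dyr = dy.reshape(B, self.in_maps, self.depth, T)
        self.grads["W"] = np.einsum("bfct,bfdt->fdc", self._x, dyr)
        return np.einsum("bfdt,fdc->bfct", dyr, self.params["W"])

    def output_shape(self, s):
        return (self.in_maps * self.depth, 1, s[2])


class DepthwiseTemporalConv(Layer):
    """Per-map temporal convolution, kernel (1, k) — the depthwise half of
    the separable convolution."""

    def __init__(self, maps: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k = k
        self.pl, self.pr = _same_pad(k)
        self.params["W"] = glorot_uniform(rng, (maps, k), k, k)

    def forward(self, x, training=False):
        self._xwin = _twin(x, self.k, self.pl, self.pr)        # (B,M,C,T,k)
        return np.einsum("bmctk,mk->bmct", self._xwin, self.params["W"])

    def backward(self, dy):
        self.grads["W"] = np.einsum("bmctk,bmct->mk", self._xwin, dy)
        wf = self.params["W"][:, ::-1]
        dywin = _twin(dy, self.k, self.k - 1 - self.pl, self.k - 1 - self.pr)
        return np.einsum("bmctk,mk->bmct", dywin, wf)


class PointwiseConv(Layer):
    """1x1 convolution mixing maps (the pointwise half of separable)."""

    def __init__(self, in_maps: int, out_maps: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = glorot_uniform(rng, (out_maps, in_maps), in_maps, out_maps)

    def forward(self, x, training=False):
        self._x = x
        return np.einsum("bmct,om->boct", x, self.params["W"])

    def backward(self, dy):
        self.grads["W"] = np.einsum("bmct,boct->om", self._x, dy)
        return np.einsum("boct,om->bmct", dy, self.params["W"])

    def output_shape(self, s):
        return (self.params["W"].shape[0], s[1], s[2])


class BatchNorm(Layer):
    """Per-map batch normalisation over (batch, channels, time)."""

    def __init__(self, maps: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(maps)
        self.params["beta"] = np.zeros(maps)
        self.running_mean = np.zeros(maps)
        self.running_var = np.ones(maps)

    def forward(self, x, training=False):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)[None, :, None, None]
            self._xhat = (x - mean[None, :, None, None]) / self._std
            return g * self._xhat + b
        mean = self.running_mean[None, :, None, None]
        std = np.sqrt(self.running_var + self.eps)[None, :, None, None]
        return g * (x - mean) / std + b

    def backward(self, dy):
        # training-mode gradient (backward only called during training)
        g = self.params["gamma"][None, :, None, None]
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads["gamma"] = np.einsum("bmct,bmct->m", dy, self._xhat)
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        dxhat = dy * g
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (dxhat - s1 / n - self._xhat * s2 / n) / self._std


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False):
        y = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._mask, self._y = x > 0, y
        return y

    def backward(self, dy):
        return dy * np.where(self._mask, 1.0, self._y + self.alpha)


class AvgPoolTime(Layer):
    """Average pooling (1, p) along time; trailing remainder truncated."""

    def __init__(self, p: int):
        super().__init__()
        self.p = p

    def forward(self, x, training=False):
        B, M, C, T = x.shape
        Tp = T // self.p
        self._in_T = T
        return x[..., :Tp * self.p].reshape(B, M, C, Tp, self.p).mean(axis=-1)

    def backward(self, dy):
        B, M, C, Tp = dy.shape
        dx = np.zeros((B, M, C, self._in_T))
        dx[..., :Tp * self.p] = np.repeat(dy / self.p, self.p, axis=-1)
        return dx

    def output_shape(self, s):
        return (s[0], s[1], s[2] // self.p)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, training=False):
        if not training or self.p <= 0:
            return x
        self._mask = self.rng.random(x.shape) >= self.p
        return x * self._mask / (1.0 - self.p)

    def backward(self, dy):
        if self.p <= 0:
            return dy
        return dy * self._mask / (1.0 - self.p)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def output_shape(self, s):
        return (int(np.prod(s)),)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T

    def output_shape(self, s):
        return (self.params["W"].shape[1],)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean NLL for integer labels y."""
    n = probs.shape[0]
    return float(-np.mean(np.log(np.maximum(probs[np.arange(n), y], 1e-12))))


def softmax_xent_grad(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(mean CE)/d(logits) for a softmax output."""
    n = probs.shape[0]
    g = probs.copy()
    g[np.arange(n), y] -= 1.0
    return g / n


class Sequential:
    """Plain layer stack with forward/backward."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        for layer in self.layers:
            for name, p in layer.params.items():
                yield layer, name, p


class Adam:
    """Adam optimiser over one or more Sequential models / layers."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer in layers:
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (id(layer), name)
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
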