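"""Minimal volumetric neural-network layers in numpy.

Provides exactly what the 3D classification network needs: 3D convolution
(3x3x3, stride 1, zero padding 1), batch normalization, ReLU, 2x2x2 max
pooling, dense layers, softmax cross-entropy and the Adam optimizer.
Tensors are NCDHW (batch, channel, depth, height, width).  Everything is
deterministic given the generator used for initialization.

Convolutions are evaluated as matrix products on an im2col expansion of
``sliding_window_view`` patches, which keeps training on desk-scale inputs
(32^3 volumes) tractable on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3D",
    "BatchNorm",
    "ReLU",
    "MaxPool3D",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3D(Layer):
    """3x3x3 convolution, stride 1, zero padding 1 (shape preserving)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        k = 3
        fan_in = in_ch * k**3
        self.W = rng.standard_normal((out_ch, in_ch, k, k, k)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(out_ch)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        # windows: (n, c, d, h, w, 3, 3, 3) -> columns (n*dhw, c*27)
        win = sliding_window_view(xp, (3, 3, 3), axis=(2, 3, 4))
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * d * h * w, -1)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        self._cols, self._shape = cols, (n, c, d, h, w)
        return out.reshape(n, d, h, w, -1).transpose(0, 4, 1, 2, 3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        out_ch = self.W.shape[0]
        g = grad.transpose(0, 2, 3, 4, 1).reshape(-1, out_ch)
        self.grads[0][...] = (g.T @ self._cols).reshape(self.W.shape)
        self.grads[1][...] = g.sum(axis=0)
        gcols = g @ self.W.reshape(out_ch, -1)  # (n*dhw, c*27)
        gcols = gcols.reshape(n, d, h, w, c, 3, 3, 3)
        gx = np.zeros((n, c, d + 2, h + 2, w + 2))
        for kd in range(3):
            for kh in range(3):
                for kw in range(3):
                    gx[:, :, kd: kd + d, kh: kh + h, kw: kw + w] += gcols[
                        :, :, :, :, :, kd, kh, kw
                    ].transpose(0, 4, 1, 2, 3)
        return gx[:, :, 1:-1, 1:-1, 1:-1]


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def _axes(self, x):
        return tuple(i for i in range(x.ndim) if i != 1)

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes, bs = self._axes(x), self._bshape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(bs)) / self._std.reshape(bs)
        self._m = x.size // x.shape[1]
        return self.gamma.reshape(bs) * self._xhat + self.beta.reshape(bs)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes, bs = self._axes(grad), self._bshape(grad)
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        g = grad * self.gamma.reshape(bs)
        return (
            g - g.mean(axis=axes).reshape(bs) - self._xhat * (g * self._xhat).mean(axis=axes).reshape(bs)
        ) / self._std.reshape(bs)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2; trailing odd slices are dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xv = x[:, :, : d2 * 2, : h2 * 2, : w2 * 2].reshape(n, c, d2, 2, h2, 2, w2, 2)
        xv = xv.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d2, h2, w2, 8)
        self._argmax = xv.argmax(axis=-1)
        self._inshape = x.shape
        return xv.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._inshape
        d2, h2, w2 = d // 2, h // 2, w // 2
        gx = np.zeros((n, c, d2, h2, w2, 8))
        np.put_along_axis(gx, self._argmax[..., None], grad[..., None], axis=-1)
        gx = gx.reshape(n, c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        out = np.zeros((n, c, d, h, w))
        out[:, :, : d2 * 2, : h2 * 2, : w2 * 2] = gx.reshape(n, c, d2 * 2, h2 * 2, w2 * 2)
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, s in zip(self.params, state[:n]):
            p[...] = s
        extra = iter(state[n:])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(extra).copy()
                layer.running_var = next(extra).copy()


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
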