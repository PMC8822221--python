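"""Minimal NumPy CNN engine: layers with explicit backward passes.

Convolutions are lowered to BLAS matrix multiplies through
``sliding_window_view`` (im2col), which keeps a 1-CPU training run of the
scaled-down U-Net in the minutes range.  All tensors are float32 in NCHW
layout.  Parameters live in ``Layer.params`` / ``Layer.grads`` dictionaries
so the Adam optimizer can iterate them generically.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base class: stateless unless it owns parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)


class Conv2D(Layer):
    """3x3 (or kxk) same-padded convolution, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.params["w"] = _he_init(rng, (c_out, c_in, k, k), c_in * k * k)
        self.params["b"] = np.zeros(c_out, dtype=F32)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        wmat = self.params["w"].reshape(self.c_out, -1)
        out = cols @ wmat.T + self.params["b"]
        if training:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        g = gout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads["w"] = (g.T @ self._cols).reshape(self.params["w"].shape)
        self.grads["b"] = g.sum(axis=0)
        gcols = g @ self.params["w"].reshape(self.c_out, -1)
        # col2im: scatter-add the kxk windows back onto the padded grid
        p = self.k // 2
        gx = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        gcols = gcols.reshape(n, h, w, c, self.k, self.k)
        for di in range(self.k):
            for dj in range(self.k):
                gx[:, :, di : di + h, dj : dj + w] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self._cols = None
        return gx[:, :, p : p + h, p : p + w]


class BatchNorm2D(Layer):
    """Per-channel batch normalization; running moments used at inference."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=F32)
        self.params["beta"] = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        self.grads["gamma"] = (gout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = gout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        gxhat = gout * g
        t1 = gxhat - gxhat.mean(axis=(0, 2, 3), keepdims=True)
        t2 = xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        return inv[None, :, None, None] * (t1 - t2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0 if training else None
        return np.maximum(x, 0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = gout * self._mask
        self._mask = None
        return g


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if training:
            self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = gout.shape
        g = self._mask * gout[:, :, :, None, :, None]
        self._mask = None
        return g.reshape(n, c, h2 * 2, w2 * 2).astype(F32)


class TransposedConv2x2(Layer):
    """Learnable 2x stride-2 upsampling: each input pixel emits a 2x2 block."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params["w"] = _he_init(rng, (c_in, c_out, 2, 2), c_in)
        self.params["b"] = np.zeros(c_out, dtype=F32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if training:
            self._x = x
        out = np.einsum("nchw,cokl->nohkwl", x, self.params["w"], optimize=True)
        out = out.reshape(n, self.c_out, h * 2, w * 2)
        return out + self.params["b"][None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, co, h2, w2 = gout.shape
        g = gout.reshape(n, co, h2 // 2, 2, w2 // 2, 2)
        self.grads["w"] = np.einsum("nchw,nohkwl->cokl", self._x, g, optimize=True)
        self.grads["b"] = gout.sum(axis=(0, 2, 3))
        gx = np.einsum("nohkwl,cokl->nchw", g, self.params["w"], optimize=True)
        self._x = None
        return gx.astype(F32)


class Softmax(Layer):
    """Channel-wise softmax head; per-pixel probabilities sum to 1."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        if training:
            self._p = p
        return p

    def backward(self, gout: np.ndarray) -> np.ndarray:
        p = self._p
        self._p = None
        return (p * (gout - (gout * p).sum(axis=1, keepdims=True))).astype(F32)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._p = p
        return p

    def backward(self, gout: np.ndarray) -> np.ndarray:
        p = self._p
        self._p = None
        return (gout * p * (1.0 - p)).astype(F32)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


class Adam:
    """Adam with default moment parameters; only the learning rate varies."""

    def __init__(self, params: list[tuple[Layer, str]], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.entries = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[k]) for layer, k in params]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, (layer, k) in enumerate(self.entries):
            g = layer.grads[k]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            layer.params[k] -= (lr * (self.m[i] / b1c) /
                                (np.sqrt(self.v[i] / b2c) + self.eps)).astype(F32)
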