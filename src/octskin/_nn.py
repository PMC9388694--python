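"""Minimal CPU neural-network layers with hand-written backpropagation.

Everything operates on channel-first batches (N, C, H, W).  Each layer caches
what its backward pass needs during forward and accumulates parameter
gradients in-place; ``backward`` returns the gradient with respect to its
input.  Convolutions use im2col + GEMM, which is the fastest pure-numpy route
at the image sizes this package trains on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "MaxPool2",
    "ConvTranspose2",
    "ConvBlock",
    "Adam",
]


class Param:
    """A trainable array with an accumulated gradient.

    ``decay=True`` marks parameters included in the L2 penalty (convolution
    and deconvolution weights; never biases or normalization parameters).
    """

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Conv2d:
    """k x k convolution, stride 1, 'same' padding (k odd) or k=1."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / (cin * ksize * ksize))
        self.W = Param(rng.normal(0.0, std, (cout, cin, ksize, ksize)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype), decay=False)
        self.k = ksize
        self.pad = ksize // 2

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        cout = self.W.value.shape[0]
        if k == 1:
            self._x1 = x
            out = np.tensordot(self.W.value[:, :, 0, 0], x, axes=([1], [1]))  # (cout, N, H, W)
            out = out.transpose(1, 0, 2, 3) + self.b.value[None, :, None, None]
            return np.ascontiguousarray(out)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)
        self._cols = cols
        self._shape = (n, c, h, w)
        wmat = self.W.value.reshape(cout, -1)
        out = cols @ wmat.T + self.b.value
        return np.ascontiguousarray(out.reshape(n, h, w, cout).transpose(0, 3, 1, 2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        cout = self.W.value.shape[0]
        if self.k == 1:
            x = self._x1
            self.W.grad[:, :, 0, 0] += np.tensordot(g, x, axes=([0, 2, 3], [0, 2, 3]))
            self.b.grad += g.sum(axis=(0, 2, 3))
            dx = np.tensordot(self.W.value[:, :, 0, 0].T, g, axes=([1], [1])).transpose(1, 0, 2, 3)
            return np.ascontiguousarray(dx)
        n, c, h, w = self._shape
        k, p = self.k, self.pad
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * w, cout)
        self.W.grad += (g2.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.W.value.reshape(cout, -1)).reshape(n, h, w, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, H, W, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j]
        return np.ascontiguousarray(dxp[:, :, p : p + h, p : p + w])


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype), decay=False)
        self.beta = Param(np.zeros(channels, dtype=dtype), decay=False)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * invstd[None, :, None, None]
        self._xhat, self._invstd, self._train = xhat, invstd, train
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += g.sum(axis=(0, 2, 3))
        dxhat = g * self.gamma.value[None, :, None, None]
        if not self._train:
            return dxhat * invstd[None, :, None, None]
        mean_d = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return invstd[None, :, None, None] * (dxhat - mean_d - xhat * mean_dx)


class LeakyReLU:
    def __init__(self, negative_slope: float = 0.01):
        self.slope = negative_slope

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._pos = x > 0
        return np.where(self._pos, x, self.slope * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._pos, g, self.slope * g)


class MaxPool2:
    """2x2 max pooling, stride 2."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        self._arg = v.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(v, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        z = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(z, self._arg[..., None], g[..., None], axis=-1)
        return np.ascontiguousarray(
            z.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        )


class ConvTranspose2:
    """2x2 transposed convolution, stride 2 (learned 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / (cin * 4))
        self.W = Param(rng.normal(0.0, std, (cin, cout, 2, 2)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype), decay=False)

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        cout = self.W.value.shape[1]
        t = np.einsum("nchw,cokl->nohkwl", x, self.W.value, optimize=True)
        out = t.reshape(n, cout, 2 * h, 2 * w) + self.b.value[None, :, None, None]
        return np.ascontiguousarray(out)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        cout = self.W.value.shape[1]
        g6 = g.reshape(n, cout, h, 2, w, 2)
        self.W.grad += np.einsum("nohkwl,nchw->cokl", g6, x, optimize=True)
        self.b.grad += g.sum(axis=(0, 2, 3))
        dx = np.einsum("nohkwl,cokl->nchw", g6, self.W.value, optimize=True)
        return np.ascontiguousarray(dx)


class ConvBlock:
    """Two (conv 3x3 -> batch norm -> leaky ReLU) stages."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, negative_slope: float = 0.01, dtype=np.float32):
        self.layers = [
            Conv2d(cin, cout, 3, rng, dtype),
            BatchNorm2d(cout, dtype=dtype),
            LeakyReLU(negative_slope),
            Conv2d(cout, cout, 3, rng, dtype),
            BatchNorm2d(cout, dtype=dtype),
            LeakyReLU(negative_slope),
        ]

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.value -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.value.dtype)
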