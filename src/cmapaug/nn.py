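"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the pieces a 2D U-Net needs — 3x3 same-padded
convolution, batch normalization, ReLU, 2x2 max pooling, 2x2 stride-2
transposed convolution, a 1x1 output convolution and the Adam optimizer —
as plain NumPy on float32 tensors in (N, C, H, W) layout.  Convolutions run
as im2col + GEMM; the input gradient of a convolution reuses the same
machinery with the 180-degree-rotated, channel-swapped kernel.

Each layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients in ``backward``; ``Sequential`` chains them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d",
    "ConvTranspose2d", "Conv1x1", "Sequential", "sigmoid", "Adam",
]

F32 = np.float32


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches of the 1-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * 9
    )


def _conv3(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None):
    """Same-padded 3x3 convolution; returns output and the im2col cache."""
    n, _, h, w = x.shape
    co = weight.shape[0]
    cols = _im2col3(x)
    y = cols @ weight.reshape(co, -1).T
    if bias is not None:
        y += bias
    return y.reshape(n, h, w, co).transpose(0, 3, 1, 2), cols


class Layer:
    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 convolution, stride 1, zero padding 1 (size preserving)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialization for ReLU nets
        self.weight = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(F32)
        self.bias = np.zeros(c_out, dtype=F32) if bias else None
        self.gweight = np.zeros_like(self.weight)
        self.gbias = np.zeros_like(self.bias) if bias else None

    def parameters(self):
        pairs = [(self.weight, self.gweight)]
        if self.bias is not None:
            pairs.append((self.bias, self.gbias))
        return pairs

    def forward(self, x, train):
        y, cols = _conv3(x, self.weight, self.bias)
        self._cols = cols if train else None
        self._shape = x.shape
        return y

    def backward(self, gy):
        n, _, h, w = self._shape
        g2 = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.gweight += (g2.T @ self._cols).reshape(self.weight.shape)
        if self.bias is not None:
            self.gbias += g2.sum(axis=0)
        # dx = conv(gy, W rotated 180deg with in/out channels swapped)
        w_t = np.ascontiguousarray(
            self.weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        )
        dx, _ = _conv3(gy, w_t, None)
        self._cols = None
        return dx


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * invstd[:, None, None]
        if train:
            self._xhat, self._invstd = xhat.astype(F32), invstd.astype(F32)
        return (self.gamma[:, None, None] * xhat + self.beta[:, None, None]).astype(F32)

    def backward(self, gy):
        xhat, invstd = self._xhat, self._invstd
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        dgamma = (gy * xhat).sum(axis=(0, 2, 3))
        dbeta = gy.sum(axis=(0, 2, 3))
        self.ggamma += dgamma
        self.gbeta += dbeta
        coeff = (self.gamma * invstd / m)[:, None, None]
        dx = coeff * (m * gy - dbeta[:, None, None] - xhat * dgamma[:, None, None])
        self._xhat = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train):
        self._pos = x > 0
        return np.where(self._pos, x, 0)

    def backward(self, gy):
        return np.where(self._pos, gy, 0)


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        windows = x.reshape(n, c, h // 2, 2, w // 2, 2)
        windows = windows.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = windows.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(windows, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        n, c, h, w = self._shape
        grid = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(grid, self._argmax[..., None], gy[..., None], axis=-1)
        grid = grid.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(grid).reshape(n, c, h, w)


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (doubles H and W)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * 4))
        self.weight = (rng.standard_normal((c_in, c_out * 4)) * scale).astype(F32)
        self.bias = np.zeros(c_out, dtype=F32)
        self.gweight = np.zeros_like(self.weight)
        self.gbias = np.zeros_like(self.bias)

    def parameters(self):
        return [(self.weight, self.gweight), (self.bias, self.gbias)]

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
        self._xr = xr if train else None
        self._shape = x.shape
        y = (xr @ self.weight).reshape(n, h, w, self.c_out, 2, 2)
        y = y.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.c_out, 2 * h, 2 * w)
        return np.ascontiguousarray(y) + self.bias[:, None, None]

    def backward(self, gy):
        n, c, h, w = self._shape
        g = gy.reshape(n, self.c_out, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        g = np.ascontiguousarray(g).reshape(-1, self.c_out * 4)
        self.gweight += self._xr.T @ g
        self.gbias += gy.sum(axis=(0, 2, 3))
        dx = (g @ self.weight.T).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        self._xr = None
        return np.ascontiguousarray(dx)


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / c_in)
        self.weight = (rng.standard_normal((c_in, c_out)) * scale).astype(F32)
        self.bias = np.zeros(c_out, dtype=F32)
        self.gweight = np.zeros_like(self.weight)
        self.gbias = np.zeros_like(self.bias)

    def parameters(self):
        return [(self.weight, self.gweight), (self.bias, self.gbias)]

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
        self._xr = xr if train else None
        self._shape = x.shape
        y = xr @ self.weight + self.bias
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gy):
        n, c, h, w = self._shape
        g = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.gweight += self._xr.T @ g
        self.gbias += g.sum(axis=0)
        dx = (g @ self.weight.T).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        self._xr = None
        return np.ascontiguousarray(dx)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=F32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    expx = np.exp(x[~pos])
    out[~pos] = expx / (1.0 + expx)
    return out


class Adam:
    """Adaptive-moment-estimation optimizer over (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
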