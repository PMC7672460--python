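"""Minimal NumPy neural-network engine used by the label-free marker CNN.

Implements exactly the layer set the marker-regression network needs —
3x3 zero-padded convolution, batch normalization, ReLU, 2x2 max pooling,
global average pooling, a dense head and a sigmoid output — with explicit
forward/backward passes and an Adam optimizer. Convolutions are evaluated
as batched GEMMs over an im2col expansion restricted to the nine kernel
offsets, which keeps both directions fully vectorized.

All computation is float32. Layers cache what their backward pass needs;
``backward`` must follow the matching ``forward`` call.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1, no bias (BN follows)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        # He initialization for ReLU nets
        std = np.sqrt(2.0 / (9 * cin))
        self.w = Param(rng.normal(0.0, std, size=(cout, 9 * cin)).astype(F32))
        self.cin, self.cout = cin, cout
        self._cols = None
        self._shape = None

    def params(self):
        return [self.w]

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = np.empty((n, 9 * c, h * w), dtype=F32)
        k = 0
        for di in range(3):
            for dj in range(3):
                cols[:, k * c:(k + 1) * c, :] = xp[:, :, di:di + h, dj:dj + w].reshape(n, c, h * w)
                k += 1
        return cols

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        if train:
            self._cols, self._shape = cols, x.shape
        y = self.w.value @ cols  # (n, cout, h*w)
        return y.reshape(n, self.cout, h, w)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        gyf = gy.reshape(n, self.cout, h * w)
        self.w.grad += np.matmul(gyf, self._cols.transpose(0, 2, 1)).sum(axis=0)
        gcols = self.w.value.T @ gyf  # (n, 9c, h*w)
        gxp = np.zeros((n, c, h + 2, w + 2), dtype=F32)
        k = 0
        for di in range(3):
            for dj in range(3):
                gxp[:, :, di:di + h, dj:dj + w] += gcols[:, k * c:(k + 1) * c, :].reshape(n, c, h, w)
                k += 1
        self._cols = None
        return gxp[:, :, 1:-1, 1:-1]


class BatchNorm2d:
    """Batch normalization over (batch, height, width) per channel."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=F32))
        self.beta = Param(np.zeros(c, dtype=F32))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        g = self.gamma.value[None, :, None, None]
        b = self.beta.value[None, :, None, None]
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu[None, :, None, None]) * invstd[None, :, None, None]
            self._cache = (xhat, invstd, x.shape)
            return g * xhat + b
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * invstd[None, :, None, None]
        return g * xhat + b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, invstd, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        sum_gy = gy.sum(axis=(0, 2, 3), keepdims=True)
        sum_gy_xhat = (gy * xhat).sum(axis=(0, 2, 3), keepdims=True)
        gx = (g * invstd[None, :, None, None] / m) * (m * gy - sum_gy - xhat * sum_gy_xhat)
        self._cache = None
        return gx.astype(F32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._mask
        self._mask = None
        return gx


class MaxPool2:
    """2x2 max pooling, stride 2."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        gxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(gxr, idx[..., None], gy[..., None], axis=-1)
        gx = gxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return gx.reshape(n, c, h, w)


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(gy[:, :, None, None] / (h * w), (n, c, h, w)).astype(F32)


class Dense:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, std, size=(cout, cin)).astype(F32))
        self.b = Param(np.zeros(cout, dtype=F32))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        gx = gy @ self.w.value
        self._x = None
        return gx


class Sigmoid:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._y * (1.0 - self._y)
        self._y = None
        return gx


class ResidualBlock:
    """conv-BN-ReLU-conv-BN plus identity shortcut, then ReLU.

    When the block widens the channel count, the shortcut zero-pads the
    extra channels (a parameter-free projection), so every convolutional
    layer in the network belongs to the main paths.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.conv1 = Conv3x3(cin, cout, rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv3x3(cout, cout, rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu_out = ReLU()

    def params(self):
        out = []
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2):
            out.extend(layer.params())
        return out

    @property
    def conv_layers(self):
        return [self.conv1, self.conv2]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        if self.cin != self.cout:
            pad = self.cout - self.cin
            shortcut = np.pad(x, ((0, 0), (0, pad), (0, 0), (0, 0)))
        else:
            shortcut = x
        return self.relu_out.forward(h + shortcut, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(gy)
        gh = self.bn2.backward(g)
        gh = self.conv2.backward(gh)
        gh = self.relu1.backward(gh)
        gh = self.bn1.backward(gh)
        gh = self.conv1.backward(gh)
        gshort = g[:, :self.cin] if self.cin != self.cout else g
        return gh + gshort


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad ** 2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. the prediction."""
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(F32)
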