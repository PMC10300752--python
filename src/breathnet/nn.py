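"""Minimal NumPy neural-network engine for 1D convolutional classifiers.

Implements exactly the layer types the residual architecture needs —
1D convolution, batch normalization, ReLU, global average pooling and a
fully connected head — each with a hand-written backward pass, plus SGD
with momentum. Forward passes in inference mode are deterministic; training
determinism follows from seeding every RNG that touches the data order and
the initial weights.

Layout conventions: activations are ``(batch, channels, length)`` float32
arrays; fully connected inputs are ``(batch, features)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "GlobalAvgPool1d",
    "Linear",
    "SGD",
    "softmax_cross_entropy",
]

_F32 = np.float32


class Param:
    """A trainable array with its gradient accumulator.

    ``decay`` marks whether weight decay applies (convolution and fully
    connected weights: yes; batch-norm scale/shift and biases: no).
    """

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = True, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=_F32)
        self.grad = np.zeros_like(self.value)
        self.decay = bool(decay)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


class Conv1d:
    """1D convolution (cross-correlation) without bias.

    Bias is omitted because every convolution in the architecture is
    followed (or, in pre-activation units, preceded) by batch normalization
    whose shift makes a bias redundant.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | None = None,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        if padding is None:
            padding = (kernel_size - 1) // 2
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.name = name
        rng = rng if rng is not None else np.random.default_rng(0)
        # He fan-in initialization, matching the residual-network lineage.
        std = np.sqrt(2.0 / (in_channels * kernel_size))
        w = rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size))
        self.weight = Param(w, decay=True, name=f"{name}.weight")
        self._cache = None

    def out_length(self, length: int) -> int:
        return (length + 2 * self.padding - self.kernel_size) // self.stride + 1

    def params(self) -> list[Param]:
        return [self.weight]

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, int]:
        n, c, length = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        else:
            xp = x
        lo = self.out_length(length)
        cols = np.empty((n, c, k, lo), dtype=_F32)
        span = s * (lo - 1) + 1
        for t in range(k):
            cols[:, :, t, :] = xp[:, :, t : t + span : s]
        return cols.reshape(n, c * k, lo), lo

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cols, lo = self._im2col(x)
        w2 = self.weight.value.reshape(self.out_channels, -1)
        y = np.matmul(w2, cols)
        self._cache = (cols, x.shape) if training else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, c, length = x_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        lo = dy.shape[2]
        w2 = self.weight.value.reshape(self.out_channels, -1)
        # dW = sum_n dy[n] @ cols[n]^T
        dw = np.tensordot(dy, cols, axes=([0, 2], [0, 2]))
        self.weight.grad += dw.reshape(self.weight.value.shape)
        dcols = np.matmul(w2.T, dy).reshape(n, c, k, lo)
        dxp = np.zeros((n, c, length + 2 * p), dtype=_F32)
        span = s * (lo - 1) + 1
        for t in range(k):
            dxp[:, :, t : t + span : s] += dcols[:, :, t, :]
        self._cache = None
        return dxp[:, :, p : p + length] if p else dxp


class BatchNorm1d:
    """Batch normalization over (batch, length) per channel."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.name = name
        self.gamma = Param(np.ones(channels), decay=False, name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), decay=False, name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        g = self.gamma.value[None, :, None]
        b = self.beta.value[None, :, None]
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(_F32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(_F32)
            self._cache = (xhat, inv_std)
            return (g * xhat + b).astype(_F32)
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None]) * inv_std[None, :, None]
        return (g * xhat + b).astype(_F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n, c, length = dy.shape
        m = n * length
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.value[None, :, None]
        sum_dy = dy.sum(axis=(0, 2))[None, :, None]
        sum_dy_xhat = (dy * xhat).sum(axis=(0, 2))[None, :, None]
        dx = (g * inv_std[None, :, None] / m) * (m * dy - sum_dy - xhat * sum_dy_xhat)
        self._cache = None
        return dx.astype(_F32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        self._mask = x > 0 if training else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class GlobalAvgPool1d:
    """Mean over the temporal axis: (n, c, l) -> (n, c)."""

    def __init__(self):
        self._length = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._length = x.shape[2] if training else None
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        length = self._length
        self._length = None
        return np.repeat(dy[:, :, None], length, axis=2) / _F32(length)


class Linear:
    """Fully connected layer with bias, input (n, features)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, name: str = "fc"):
        self.in_features = in_features
        self.out_features = out_features
        self.name = name
        rng = rng if rng is not None else np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, std, size=(in_features, out_features)),
                            decay=True, name=f"{name}.weight")
        self.bias = Param(np.zeros(out_features), decay=False, name=f"{name}.bias")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x if training else None
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        self._cache = None
        return dy @ self.weight.value.T


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch of integer labels.

    Returns ``(loss, dlogits, probs)`` where ``dlogits`` is the gradient of
    the mean loss with respect to the logits.
    """
    n = logits.shape[0]
    shifted = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    probs = exp / exp.sum(axis=1, keepdims=True)
    eps = np.finfo(np.float64).tiny
    loss = float(-np.log(probs[np.arange(n), labels] + eps).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits.astype(_F32), probs


class SGD:
    """Stochastic gradient descent with classical momentum.

    Update (per parameter): v <- mu * v + (grad + wd * w); w <- w - lr * v,
    with weight decay applied only to parameters flagged ``decay``.
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if p.decay and self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= _F32(self.lr) * v
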