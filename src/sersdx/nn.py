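"""Minimal 1-D convolutional network with manual backpropagation.

Implemented directly on NumPy: convolutions are lowered to GEMM via
strided im2col views, so the heavy lifting happens in BLAS and a small
network trains on a full synthetic cohort in minutes on one CPU.  Every
layer's ``backward`` returns the gradient with respect to its input, which
makes exact input-space gradients (for saliency attribution) available for
free at the bottom of the stack.

Numerics: parameters and activations are float32; the binary cross-entropy
is computed on logits (softplus form) for stability; He-uniform
initialization for conv and dense weights.
"""

from __future__ import annotations

import copy

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .errors import SersdxError


class TrainingError(SersdxError):
    """Raised when optimization diverges (non-finite loss)."""


def _he_uniform(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params_and_grads(self):
        return []


class Conv1d(Layer):
    """Valid (no padding) 1-D convolution, stride 1: (N, C, L) -> (N, F, L-K+1)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        self.k = kernel_size
        self.W = _he_uniform(rng, in_channels * kernel_size, (out_channels, in_channels, kernel_size))
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, l = x.shape
        lo = l - self.k + 1
        sn, sc, sl = x.strides
        cols = as_strided(x, shape=(n, lo, c, self.k), strides=(sn, sl, sc, sl))
        return cols.reshape(n * lo, c * self.k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(np.ascontiguousarray(x))
        n, c, l = x.shape
        lo = l - self.k + 1
        out = self._cols @ self.W.reshape(len(self.W), -1).T + self.b
        return out.reshape(n, lo, -1).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, f, lo = grad.shape
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(n * lo, f)
        self.dW = (g2.T @ self._cols).reshape(self.W.shape)
        self.db = g2.sum(axis=0)
        dcols = (g2 @ self.W.reshape(f, -1)).reshape(n, lo, -1, self.k)
        dx = np.zeros(self._x_shape, dtype=grad.dtype)
        for j in range(self.k):  # k is small (default 7); scatter-add per tap
            dx[:, :, j : j + lo] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dx

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; trailing channels that do not fill a
    window are dropped (floor division), matching common framework defaults."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, l = x.shape
        lo = l // self.size
        xr = x[:, :, : lo * self.size].reshape(n, c, lo, self.size)
        self._arg = xr.argmax(axis=3)
        self._in_len = l
        return np.take_along_axis(xr, self._arg[..., None], axis=3)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, lo = grad.shape
        dxr = np.zeros((n, c, lo, self.size), dtype=grad.dtype)
        np.put_along_axis(dxr, self._arg[..., None], grad[..., None], axis=3)
        dx = np.zeros((n, c, self._in_len), dtype=grad.dtype)
        dx[:, :, : lo * self.size] = dxr.reshape(n, c, lo * self.size)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = _he_uniform(rng, in_features, (in_features, out_features))
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Network:
    """A plain layer stack mapping (N, C, L) input to an (N,) logit vector."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x.reshape(-1)

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(logit); returns d(loss)/d(input)."""
        grad = dlogit.reshape(-1, 1).astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params_and_grads(self):
        return [pg for layer in self.layers for pg in layer.params_and_grads()]

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params_and_grads()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for (p, _), saved in zip(self.params_and_grads(), state):
            p[...] = saved

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(logit)/d(input) for every row of x, shape = x.shape."""
        self.forward(x)
        return self.backward(np.ones(len(x), dtype=np.float32))


def build_cnn(
    input_length: int,
    conv_blocks: list[tuple[int, int]],
    fc_sizes: list[int],
    rng: np.random.Generator,
    pool_size: int = 2,
) -> Network:
    """conv -> ReLU -> max-pool blocks, flatten, dense stack, scalar logit."""
    layers: list[Layer] = []
    channels, length = 1, input_length
    for filters, kernel in conv_blocks:
        if length < kernel:
            raise TrainingError(f"input length {length} shorter than kernel {kernel}")
        layers += [Conv1d(channels, filters, kernel, rng), ReLU(), MaxPool1d(pool_size)]
        channels, length = filters, (length - kernel + 1) // pool_size
    layers.append(Flatten())
    width = channels * length
    for fc in fc_sizes:
        layers += [Dense(width, fc, rng), ReLU()]
        width = fc
    layers.append(Dense(width, 1, rng))
    return Network(layers)


class Adam:
    def __init__(self, network: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.network = network
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in network.params_and_grads()]
        self.v = [np.zeros_like(p) for p, _ in network.params_and_grads()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (p, g) in enumerate(self.network.params_and_grads()):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, d(loss)/d(logits))."""
    z, y = logits.astype(np.float64), targets.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (1.0 / (1.0 + np.exp(-z)) - y) / len(z)
    return loss, grad.astype(np.float32)
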