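"""Minimal numpy neural-network layers used by the classifier.

Layers operate on NHWC float32 batches. Convolution is computed as an
im2col + matmul so the heavy lifting is a single BLAS call; the backward
pass scatters gradients back with ``np.add.at``. Only what the package
needs exists here: Conv2D ("same" padding, stride 1), ReLU, 2×2 max
pooling, Flatten, Dense, a fused softmax cross-entropy loss, and Adam.
Initialization is He-normal from a caller-supplied Generator, so a fixed
seed gives bit-identical networks.
"""

from __future__ import annotations

import numpy as np


class Layer:
    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """3×3 (or k×k) convolution, stride 1, zero "same" padding, NHWC."""

    trainable = True

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        k = kernel_size
        fan_in = k * k * in_channels
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((fan_in, out_channels)) * scale).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.k = k
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # windows: (N, H, W, C, k, k) -> (N*H*W, k*k*C)
        n, h, w, c = x.shape
        cols = windows.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * c)
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        cols = self._im2col(x)
        self._cols = cols
        n, h, w, _ = x.shape
        out = cols @ self.W + self.b
        return out.reshape(n, h, w, self.out_channels)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._x_shape
        g = grad.reshape(n * h * w, self.out_channels).astype(np.float32)
        self.dW = self._cols.T @ g
        self.db = g.sum(axis=0)
        dcols = g @ self.W.T  # (N*H*W, k*k*C)
        k, c, p = self.k, self.in_channels, self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        dcols = dcols.reshape(n, h, w, k, k, c)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class MaxPool2D(Layer):
    """2×2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        self._xt = xt
        out = xt.max(axis=(2, 4))
        self._out = out
        self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        mask = self._xt == self._out[:, :, None, :, None, :]
        # split ties evenly so gradient mass is conserved
        counts = mask.sum(axis=(2, 4), keepdims=True)
        g = (mask / counts) * grad[:, :, None, :, None, :]
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, : h2 * 2, : w2 * 2, :] = g.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)
        self.W = (rng.standard_normal((in_dim, out_dim)) * scale).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        ws = list(weights)
        for layer in self.layers:
            if isinstance(layer, (Conv2D, Dense)):
                layer.W = ws.pop(0).copy()
                layer.b = ws.pop(0).copy()
        if ws:
            raise ValueError("weight list does not match network structure")


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits.

    ``y`` holds integer class indices.
    """
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.mean(np.log(np.clip(p[np.arange(n), y], 1e-12, None)))
    grad = p
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Adam:
    """Adaptive-moment optimizer over a flat parameter list (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
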