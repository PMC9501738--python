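"""Minimal 1-D convolutional network engine in NumPy.

Implements exactly the layer set the VGG-style spectral classifier needs —
conv1d (kernel 3, stride 1, pad 1), batch normalization, ELU, max-pool of
size 2, flatten, dense, dropout — with hand-derived backward passes and an
Adam optimizer. Shapes follow the (batch, channels, length) convention.
He-normal initialization throughout, driven by an explicit Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "elu",
    "softmax",
    "cross_entropy_loss",
    "lr_schedule",
    "Conv1d",
    "BatchNorm1d",
    "Elu",
    "MaxPool1d",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
]


def elu(x, alpha: float = 1.0):
    """Exponential linear unit: ``x`` for x > 0, ``alpha*(exp(x) - 1)`` otherwise."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, alpha * np.expm1(x))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift-invariant softmax: subtracts the max so large logits cannot overflow."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_loss(p: np.ndarray, labels_onehot: np.ndarray) -> float:
    """Mean categorical cross-entropy ``-sum_ij label_ij log p_ij / batch``.

    ``p`` rows are probability vectors; the log is clamped at 1e-12.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    labels_onehot = np.atleast_2d(np.asarray(labels_onehot, dtype=float))
    if p.shape != labels_onehot.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {labels_onehot.shape}")
    return float(-(labels_onehot * np.log(np.maximum(p, 1e-12))).sum() / p.shape[0])


def lr_schedule(t: float, eta0: float, k: float) -> float:
    """Inverse-time learning-rate decay ``eta0 / (1 + k*t)`` for epoch ``t``."""
    if t < 0 or eta0 <= 0 or k < 0:
        raise ValueError("require t >= 0, eta0 > 0, k >= 0")
    return eta0 / (1.0 + k * t)


class Layer:
    """Base layer: parameter-holding layers override params/grads."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Same-length 1-D convolution: kernel 3, stride 1, zero pad 1 by default."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, pad: int = 1,
                 rng: np.random.Generator | None = None):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * kernel))  # He-normal fan-in
        self.W = rng.normal(0.0, scale, (c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.pad = pad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        B, C, L = x.shape
        k = self.W.shape[2]
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        # (B, C, L_out, k) sliding windows
        self._windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        self._in_shape = x.shape
        y = np.tensordot(self._windows, self.W, axes=([1, 3], [1, 2]))
        return y.transpose(0, 2, 1) + self.b[None, :, None]

    def backward(self, g):
        B, C, L = self._in_shape
        k = self.W.shape[2]
        self.dW[...] = np.tensordot(g, self._windows, axes=([0, 2], [0, 2]))
        self.db[...] = g.sum(axis=(0, 2))
        dxp = np.zeros((B, C, L + 2 * self.pad))
        for t in range(k):
            # dxp[:, :, t:t+L_out] accumulates g convolved with W[:, :, t]
            dxp[:, :, t:t + g.shape[2]] += np.tensordot(
                g, self.W[:, :, t], axes=([1], [0])
            ).transpose(0, 2, 1)
        return dxp[:, :, self.pad:self.pad + L]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None]
        self._xhat = (x - mean[None, :, None]) / self._std
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, g):
        B, C, L = g.shape
        n = B * L
        self.dgamma[...] = (g * self._xhat).sum(axis=(0, 2))
        self.dbeta[...] = g.sum(axis=(0, 2))
        gx = g * self.gamma[None, :, None]
        # standard batch-norm gradient through mean and variance
        return (gx - gx.mean(axis=(0, 2), keepdims=True)
                - self._xhat * (gx * self._xhat).sum(axis=(0, 2), keepdims=True) / n
                ) / self._std


class Elu(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train):
        self._out = elu(x, self.alpha)
        self._x = x
        return self._out

    def backward(self, g):
        return g * np.where(self._x > 0, 1.0, self._out + self.alpha)


class MaxPool1d(Layer):
    """Max pooling of size 2, stride 2; a trailing odd element is dropped."""

    def forward(self, x, train):
        B, C, L = x.shape
        L2 = (L // 2) * 2
        pairs = x[:, :, :L2].reshape(B, C, L2 // 2, 2)
        self._argmax = pairs.argmax(axis=3)
        self._in_shape = x.shape
        return pairs.max(axis=3)

    def backward(self, g):
        B, C, L = self._in_shape
        dx = np.zeros((B, C, L))
        Lp = g.shape[2]
        b, c, l = np.meshgrid(np.arange(B), np.arange(C), np.arange(Lp), indexing="ij")
        dx[b, c, 2 * l + self._argmax] = g
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def state(self) -> list[np.ndarray]:
        """Copies of all parameters plus batch-norm running statistics."""
        out = [p.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                out += [layer.running_mean.copy(), layer.running_var.copy()]
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.params()
        for p, s in zip(params, state[: len(params)]):
            p[...] = s
        extra = iter(state[len(params):])
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = next(extra)
                layer.running_var[...] = next(extra)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
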