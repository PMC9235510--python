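"""Minimal NumPy feed-forward stack: dense / batch-norm / dropout layers,
reverse-mode gradients, and an Adam optimizer.

Float32 throughout; every source of randomness (init, dropout masks,
minibatch order) flows through explicit ``numpy.random.Generator`` objects so
training runs are reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        s = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-s, s, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm(Layer):
    """Batch normalization with running statistics for eval mode."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n, dtype=DTYPE)
        self.beta = np.zeros(n, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train, rng=None):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
            self._istd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean) * self._istd
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        n = dout.shape[0]
        xhat, istd = self._xhat, self._istd
        self.dgamma[...] = (dout * xhat).sum(axis=0)
        self.dbeta[...] = dout.sum(axis=0)
        dxhat = dout * self.gamma
        return (
            istd / n * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        ).astype(DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def forward(self, x, train, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout: identity in eval mode."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, train, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(DTYPE) / (1 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


class Adam:
    """Adaptive-moment gradient descent over a fixed parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - y
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff.astype(DTYPE)


def bce_with_logits_loss(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits, with gradient."""
    z = logits
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = sigmoid(z)
    return loss, ((p - y) / z.size).astype(DTYPE)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=DTYPE)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
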