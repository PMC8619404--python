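"""Minimal 1-D convolutional network engine in numpy.

Implements exactly the pieces the benchmark needs — valid-mode 1-D
convolution, ReLU, width-2 max pooling, dense layers, a softmax
cross-entropy head and the Adam optimizer — with explicit seeding
throughout.  Inputs are N x L x C one-hot peptide tensors.

The engine is intentionally small: forward/backward passes are vectorized
(im2col for convolutions), parameters live in plain numpy arrays, and a
model is just a list of layers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class ConfigurationError(ValueError):
    """Raised when a network's spatial dimension collapses at build time."""


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-mode 1-D convolution: (N, L, C_in) -> (N, L-k+1, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        scale = np.sqrt(2.0 / (kernel * c_in))  # He initialization
        self.W = (rng.standard_normal((kernel, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] < self.kernel:
            raise ConfigurationError(
                f"spatial length {x.shape[1]} < kernel {self.kernel}"
            )
        # (N, L-k+1, C_in, k) -> (N, L', k, C_in)
        cols = sliding_window_view(x, self.kernel, axis=1).transpose(0, 1, 3, 2)
        self._cols = cols
        n, lp = cols.shape[0], cols.shape[1]
        flat = cols.reshape(n, lp, self.kernel * self.c_in)
        w = self.W.reshape(self.kernel * self.c_in, self.c_out)
        return flat @ w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, lp, _ = dy.shape
        flat = self._cols.reshape(n, lp, self.kernel * self.c_in)
        dw = np.tensordot(flat, dy, axes=([0, 1], [0, 1]))
        self.grads[0][...] = dw.reshape(self.W.shape)
        self.grads[1][...] = dy.sum(axis=(0, 1))
        dx = np.zeros((n, lp + self.kernel - 1, self.c_in), dtype=dy.dtype)
        for o in range(self.kernel):
            dx[:, o : o + lp, :] += dy @ self.W[o].T
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1D(Layer):
    """Width-2, stride-2 max pooling; odd trailing position is dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, L, c = x.shape
        if L < 2:
            raise ConfigurationError(f"spatial length {L} < pool width 2")
        L2 = L // 2
        self._in_len = L
        pairs = x[:, : 2 * L2].reshape(n, L2, 2, c)
        self._argmax = pairs.argmax(axis=2)
        return pairs.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, L2, c = dy.shape
        dpairs = np.zeros((n, L2, 2, c), dtype=dy.dtype)
        idx_n, idx_l, idx_c = np.ogrid[:n, :L2, :c]
        dpairs[idx_n, idx_l, self._argmax, idx_c] = dy
        dx = np.zeros((n, self._in_len, c), dtype=dy.dtype)
        dx[:, : 2 * L2] = dpairs.reshape(n, 2 * L2, c)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.W = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax: exp(x_i) / sum_j exp(x_j), numerically shifted."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """A feed-forward stack of layers with a 2-way softmax head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        """Cross-entropy loss on one batch plus a full backward pass."""
        logits = self.forward(x)
        p = softmax(logits)
        n = x.shape[0]
        eps = 1e-12
        loss = -np.log(p[np.arange(n), y] + eps).mean()
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dy = dlogits
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return float(loss)

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters))

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters, state):
            p[...] = s


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
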