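"""Minimal NumPy neural-network kernel used by the gait classifiers.

Implements exactly the layers the package's models need — 2-D "same"
convolution (im2col), dense, ReLU, flatten, a single LSTM layer — with
hand-written backprop, a softmax/cross-entropy head and an Adam optimizer.
Determinism: one ``numpy.random.Generator`` drives parameter initialization
and per-epoch batch shuffling, so a fixed seed reproduces training on the
same platform.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, DataError


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax: positive, sums to 1, shift-invariant."""
    logits = np.asarray(logits, dtype=float)
    if logits.size == 0:
        raise DataError("softmax: empty input")
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    """Mean negative log-probability of the true class over a batch.

    ``probs`` rows must lie on the simplex; zero probability at a true class
    is clamped at ``eps``.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    onehot = np.atleast_2d(np.asarray(onehot, dtype=float))
    if probs.shape != onehot.shape:
        raise DataError(f"shape mismatch: probs {probs.shape} vs labels {onehot.shape}")
    p_true = (probs * onehot).sum(axis=1)
    return float(-np.mean(np.log(np.maximum(p_true, eps))))


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.w.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Conv2D(Layer):
    """3x3 (configurable) same-padding convolution, stride 1, via im2col.

    Input/output layout is (N, H, W, C) — channels last.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3) -> None:
        super().__init__()
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = kernel * kernel * c_in
        self.w = rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _im2col(self, x):
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((n, h, w, k * k * c))
        for di in range(k):
            for dj in range(k):
                patch = xp[:, di:di + h, dj:dj + w, :]
                cols[..., (di * k + dj) * c:(di * k + dj + 1) * c] = patch
        return cols

    def forward(self, x):
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        n, h, w, _ = x.shape
        out = self._cols.reshape(n * h * w, -1) @ self.w + self.b
        return out.reshape(n, h, w, self.c_out)

    def backward(self, g):
        n, h, w, c = self._x_shape
        k, p = self.k, self.k // 2
        g2 = g.reshape(n * h * w, self.c_out)
        self.grads[0][...] = self._cols.reshape(n * h * w, -1).T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        dcols = (g2 @ self.w.T).reshape(n, h, w, k * k * c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for di in range(k):
            for dj in range(k):
                dxp[:, di:di + h, dj:dj + w, :] += \
                    dcols[..., (di * k + dj) * c:(di * k + dj + 1) * c]
        return dxp[:, p:p + h, p:p + w, :]


class LSTMLast(Layer):
    """Single LSTM layer over (N, T, C); emits the final hidden state.

    Gate order in the stacked weight matrices is (input, forget, cell,
    output); the forget-gate bias starts at 1 so early training does not
    wash out the cell state.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.nh = n_hidden
        s_x = np.sqrt(1.0 / n_in)
        s_h = np.sqrt(1.0 / n_hidden)
        self.wx = rng.uniform(-s_x, s_x, size=(n_in, 4 * n_hidden))
        self.wh = rng.uniform(-s_h, s_h, size=(n_hidden, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden)
        self.b[n_hidden:2 * n_hidden] = 1.0
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))

    def forward(self, x):
        n, t, _ = x.shape
        nh = self.nh
        h = np.zeros((n, nh))
        c = np.zeros((n, nh))
        self._x = x
        self._cache = []
        for step in range(t):
            z = x[:, step] @ self.wx + h @ self.wh + self.b
            i = self._sigmoid(z[:, :nh])
            f = self._sigmoid(z[:, nh:2 * nh])
            g = np.tanh(z[:, 2 * nh:3 * nh])
            o = self._sigmoid(z[:, 3 * nh:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
        return h

    def backward(self, dh_last):
        n, t, c_in = self._x.shape
        nh = self.nh
        for gr in self.grads:
            gr[...] = 0.0
        dx = np.zeros_like(self._x)
        dh = dh_last
        dc = np.zeros((n, nh))
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[step]
            do = dh * tc
            dc = dc + dh * o * (1 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o),
            ], axis=1)
            self.grads[0] += self._x[:, step].T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, step] = dz @ self.wx.T
            dh = dz @ self.wh.T
            dc = dc * f
        return dx


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Network:
    """Feed-forward layer stack with a softmax/cross-entropy head."""

    def __init__(self, layers: list[Layer], n_classes: int) -> None:
        self.layers = layers
        self.n_classes = n_classes

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def fit(self, x: np.ndarray, y: np.ndarray, epochs: int, batch_size: int,
            lr: float, rng: np.random.Generator) -> list[float]:
        """Mini-batch Adam training; returns the per-epoch mean batch loss."""
        if epochs < 1:
            raise ConfigError("epochs must be >= 1; an untrained model is not a model")
        n = x.shape[0]
        if n == 0:
            raise DataError("empty training set")
        onehot = np.eye(self.n_classes)[y]
        opt = Adam(self.params, lr=lr)
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                probs = softmax(self.forward(x[idx]))
                losses.append(cross_entropy(probs, onehot[idx]))
                g = (probs - onehot[idx]) / len(idx)
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                opt.step(self.grads)
            history.append(float(np.mean(losses)))
        return history
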