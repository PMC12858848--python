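"""Minimal 1-D convolutional network framework (numpy, reverse-mode by hand).

Implements exactly the pieces the stress classifier needs — same-padded 1-D
convolutions, ReLU, stride-1 max pooling, dense layers, global average
pooling, an Inception-style multi-kernel block, soft-attention fusion, a
softmax cross-entropy loss, and Adam — with explicit ``forward``/``backward``
methods per layer.  Every gradient is checked against finite differences in
the test suite.

Shapes follow the (batch, channels, time) convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution (odd kernel length)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        assert k % 2 == 1
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in, k)))
        self.b = Param(np.zeros(c_out))
        self.k = k

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        p = self.k // 2
        self._T = x.shape[2]
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        self._cols = sliding_window_view(xp, self.k, axis=2)  # (B, C, T, k)
        return np.einsum("ocj,bctj->bot", self.W.value, self._cols, optimize=True) + self.b.value[:, None]

    def backward(self, dy):
        p = self.k // 2
        self.W.grad += np.einsum("bot,bctj->ocj", dy, self._cols, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2))
        dcols = np.einsum("ocj,bot->bctj", self.W.value, dy, optimize=True)
        B, C = dcols.shape[0], dcols.shape[1]
        dxp = np.zeros((B, C, self._T + 2 * p))
        for j in range(self.k):
            dxp[:, :, j : j + self._T] += dcols[:, :, :, j]
        return dxp[:, :, p : p + self._T]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1dSame(Layer):
    """Stride-1 max pooling with same padding (odd window)."""

    def __init__(self, k: int = 3):
        assert k % 2 == 1
        self.k = k

    def forward(self, x):
        p = self.k // 2
        self._shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)), constant_values=-np.inf)
        cols = sliding_window_view(xp, self.k, axis=2)
        self._arg = np.argmax(cols, axis=3)
        return np.max(cols, axis=3)

    def backward(self, dy):
        p = self.k // 2
        B, C, T = self._shape
        dxp = np.zeros((B, C, T + 2 * p))
        for j in range(self.k):
            m = self._arg == j
            contrib = np.where(m, dy, 0.0)
            dxp[:, :, j : j + T] += contrib
        return dxp[:, :, p : p + T]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class GlobalAvgPool(Layer):
    """(B, C, T) -> (B, C) mean over time."""

    def forward(self, x):
        self._T = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._T, axis=2) / self._T


class InceptionBlock(Layer):
    """Parallel 1/3/5-kernel convolutions plus a max-pool + 1-kernel path.

    The four paths each produce ``n_filters`` channels and are concatenated,
    so the output has ``4 * n_filters`` channels and unchanged length.
    """

    def __init__(self, c_in: int, n_filters: int, rng: np.random.Generator):
        self.convs = [Conv1d(c_in, n_filters, k, rng) for k in (1, 3, 5)]
        self.pool = MaxPool1dSame(3)
        self.pool_conv = Conv1d(c_in, n_filters, 1, rng)
        self.acts = [ReLU() for _ in range(4)]
        self.n_filters = n_filters

    def params(self):
        out = []
        for c in self.convs + [self.pool_conv]:
            out.extend(c.params())
        return out

    def forward(self, x):
        if x.shape[2] < 5:
            raise ValueError("inception block needs input length >= 5")
        outs = [a.forward(c.forward(x)) for c, a in zip(self.convs, self.acts[:3])]
        outs.append(self.acts[3].forward(self.pool_conv.forward(self.pool.forward(x))))
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        nf = self.n_filters
        parts = [dy[:, i * nf : (i + 1) * nf] for i in range(4)]
        dx = sum(
            c.backward(a.backward(p))
            for c, a, p in zip(self.convs, self.acts[:3], parts[:3])
        )
        dx = dx + self.pool.backward(self.pool_conv.backward(self.acts[3].backward(parts[3])))
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class SoftAttention(Layer):
    """Additive soft attention over modality embeddings.

    Scores u_m = v · tanh(W e_m + b); weights α = softmax_m(u);
    fused = Σ_m α_m e_m.  Input (B, M, d), output (B, d); weights are kept
    on the instance after each forward pass for interpretability.
    """

    def __init__(self, d: int, attn_dim: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(1.0 / d), size=(d, attn_dim)))
        self.b = Param(np.zeros(attn_dim))
        self.v = Param(rng.normal(0.0, np.sqrt(1.0 / attn_dim), size=attn_dim))
        self.alpha: np.ndarray | None = None

    def params(self):
        return [self.W, self.b, self.v]

    def forward(self, E):
        self._E = E
        self._s = np.tanh(E @ self.W.value + self.b.value)      # (B, M, a)
        u = self._s @ self.v.value                              # (B, M)
        u = u - u.max(axis=1, keepdims=True)
        ex = np.exp(u)
        self.alpha = ex / ex.sum(axis=1, keepdims=True)
        return np.einsum("bm,bmd->bd", self.alpha, E)

    def backward(self, df):
        E, s, a = self._E, self._s, self.alpha
        dalpha = np.einsum("bd,bmd->bm", df, E)
        dE = a[:, :, None] * df[:, None, :]
        du = a * (dalpha - (a * dalpha).sum(axis=1, keepdims=True))
        self.v.grad += np.einsum("bm,bma->a", du, s)
        ds = du[:, :, None] * self.v.value[None, None, :]
        dh = ds * (1.0 - s**2)
        self.W.grad += np.einsum("bma,bmd->da", dh, E)
        self.b.grad += dh.sum(axis=(0, 1))
        dE += dh @ self.W.value.T
        return dE


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p.value -= self.lr * mh / (np.sqrt(vh) + self.eps)


def n_parameters(layer: Layer) -> int:
    return sum(p.value.size for p in layer.params())
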