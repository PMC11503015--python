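"""Minimal NumPy neural-network layers with exact analytic gradients.

The layer set is exactly what the multi-branch gait network needs: valid
(no-padding) 1-D and 2-D convolutions, max pooling, dense layers, ReLU, gated
recurrent units, and the two losses (softmax cross-entropy, mean squared
error), plus an Adam optimizer.  Every layer caches its forward activations
and implements ``backward`` returning the gradient with respect to its input
while accumulating parameter gradients; correctness is pinned by numerical
gradient checks in the test suite.

Conventions: batches lead, time/space next, channels last —
1-D signals are (B, T, C), 2-D maps are (B, H, W, C).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, DataError

__all__ = [
    "Param", "Layer", "Dense", "ReLU", "Conv1d", "MaxPool1d", "Conv2d",
    "MaxPool2d", "Flatten", "GRU", "GRUStack", "Sequential",
    "softmax", "softmax_cross_entropy", "mse_loss", "Adam", "glorot",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name


def glorot(rng: np.random.Generator, shape: tuple[int, ...],
           fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        self.w = Param(glorot(rng, (n_in, n_out), n_in, n_out), "dense.w")
        self.b = Param(np.zeros(n_out), "dense.b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.w.value.shape[0]:
            raise DataError(
                f"dense layer expects {self.w.value.shape[0]} inputs, got {x.shape[-1]}"
            )
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T

    def params(self) -> list[Param]:
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Conv1d(Layer):
    """Valid 1-D convolution, stride 1: (B, T, C_in) -> (B, T-k+1, C_out)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3) -> None:
        fan_in = kernel * c_in
        self.w = Param(glorot(rng, (kernel, c_in, c_out), fan_in, c_out), "conv1d.w")
        self.b = Param(np.zeros(c_out), "conv1d.b")
        self.kernel = kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        if x.shape[1] < k:
            raise DataError(f"input length {x.shape[1]} shorter than kernel {k}")
        self._x = x
        win = sliding_window_view(x, k, axis=1)  # (B, T-k+1, C, k)
        return np.einsum("btcj,jcl->btl", win, self.w.value, optimize=True) + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, k = self._x, self.kernel
        win = sliding_window_view(x, k, axis=1)
        self.w.grad += np.einsum("btcj,btl->jcl", win, g, optimize=True)
        self.b.grad += g.sum(axis=(0, 1))
        gx = np.zeros_like(x)
        t_out = g.shape[1]
        for j in range(k):
            gx[:, j: j + t_out] += g @ self.w.value[j].T
        return gx

    def params(self) -> list[Param]:
        return [self.w, self.b]


class MaxPool1d(Layer):
    """Non-overlapping max pooling (size=stride), trailing remainder dropped."""

    def __init__(self, size: int = 2) -> None:
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, c = x.shape
        t_out = t // self.size
        blocks = x[:, : t_out * self.size].reshape(b, t_out, self.size, c)
        self._arg = blocks.argmax(axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(blocks, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, t, c = self._in_shape
        t_out = g.shape[1]
        gb = np.zeros((b, t_out, self.size, c))
        np.put_along_axis(gb, self._arg[:, :, None, :], g[:, :, None, :], axis=2)
        gx = np.zeros((b, t, c))
        gx[:, : t_out * self.size] = gb.reshape(b, t_out * self.size, c)
        return gx


class Conv2d(Layer):
    """Valid 2-D convolution: (B, H, W, C_in) -> (B, H', W', C_out) with
    H' = floor((H - k) / stride) + 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 2) -> None:
        fan_in = kernel * kernel * c_in
        self.w = Param(glorot(rng, (kernel, kernel, c_in, c_out), fan_in, c_out),
                       "conv2d.w")
        self.b = Param(np.zeros(c_out), "conv2d.b")
        self.kernel, self.stride = kernel, stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        if x.shape[1] < k or x.shape[2] < k:
            raise DataError("spatial input smaller than kernel")
        self._x = x
        win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]
        # win: (B, H', W', C, k, k)
        self._win = win
        return np.einsum("bpqcij,ijcl->bpql", win, self.w.value, optimize=True) + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        self.w.grad += np.einsum("bpqcij,bpql->ijcl", self._win, g, optimize=True)
        self.b.grad += g.sum(axis=(0, 1, 2))
        gx = np.zeros_like(self._x)
        p, q = g.shape[1], g.shape[2]
        for i in range(k):
            for j in range(k):
                contrib = np.einsum("bpql,cl->bpqc", g, self.w.value[i, j], optimize=True)
                gx[:, i: i + s * p: s, j: j + s * q: s] += contrib
        return gx

    def params(self) -> list[Param]:
        return [self.w, self.b]


class MaxPool2d(Layer):
    def __init__(self, size: int = 2) -> None:
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        s = self.size
        ho, wo = h // s, w // s
        blocks = x[:, : ho * s, : wo * s].reshape(b, ho, s, wo, s, c)
        flat = blocks.transpose(0, 1, 3, 2, 4, 5).reshape(b, ho, wo, s * s, c)
        self._arg = flat.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        s = self.size
        ho, wo = g.shape[1], g.shape[2]
        gf = np.zeros((b, ho, wo, s * s, c))
        np.put_along_axis(gf, self._arg[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gb = gf.reshape(b, ho, wo, s, s, c).transpose(0, 1, 3, 2, 4, 5)
        gx = np.zeros((b, h, w, c))
        gx[:, : ho * s, : wo * s] = gb.reshape(b, ho * s, wo * s, c)
        return gx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class GRU(Layer):
    """Single gated-recurrent-unit layer over (B, T, D) -> (B, T, H).

    Gate order in the packed weight matrices is (reset, update, candidate),
    with a separate bias on the hidden contribution to the candidate so the
    reset gate multiplies the *biased* hidden term.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator) -> None:
        self.n_in, self.hidden = n_in, hidden
        self.wx = Param(glorot(rng, (n_in, 3 * hidden), n_in, hidden), "gru.wx")
        self.wh = Param(glorot(rng, (hidden, 3 * hidden), hidden, hidden), "gru.wh")
        self.bx = Param(np.zeros(3 * hidden), "gru.bx")
        self.bh = Param(np.zeros(3 * hidden), "gru.bh")

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != self.n_in:
            raise DataError(f"GRU expects (B, T, {self.n_in}), got {x.shape}")
        b, t, _ = x.shape
        hdim = self.hidden
        h = np.zeros((b, hdim))
        gx_all = x @ self.wx.value + self.bx.value  # (B, T, 3H)
        self._x = x
        self._cache = []
        out = np.empty((b, t, hdim))
        for step in range(t):
            gx = gx_all[:, step]
            gh = h @ self.wh.value + self.bh.value
            r = _sigmoid(gx[:, :hdim] + gh[:, :hdim])
            z = _sigmoid(gx[:, hdim:2 * hdim] + gh[:, hdim:2 * hdim])
            ghn = gh[:, 2 * hdim:]
            n = np.tanh(gx[:, 2 * hdim:] + r * ghn)
            h_new = (1.0 - z) * n + z * h
            self._cache.append((h, r, z, n, ghn))
            h = h_new
            out[:, step] = h
        return out

    def backward(self, g_seq: np.ndarray) -> np.ndarray:
        b, t, _ = self._x.shape
        hdim = self.hidden
        gx_all = np.zeros((b, t, 3 * hdim))
        dh = np.zeros((b, hdim))
        gwh = np.zeros_like(self.wh.value)
        gbh = np.zeros_like(self.bh.value)
        for step in range(t - 1, -1, -1):
            dh = dh + g_seq[:, step]
            h_prev, r, z, n, ghn = self._cache[step]
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_next = dh * z
            dn_pre = dn * (1.0 - n * n)
            dghn = dn_pre * r
            dr = dn_pre * ghn
            dr_pre = dr * r * (1.0 - r)
            dz_pre = dz * z * (1.0 - z)
            dgx = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
            dgh = np.concatenate([dr_pre, dz_pre, dghn], axis=1)
            gx_all[:, step] = dgx
            gwh += h_prev.T @ dgh
            gbh += dgh.sum(axis=0)
            dh = dh_next + dgh @ self.wh.value.T
        self.wh.grad += gwh
        self.bh.grad += gbh
        flat = gx_all.reshape(b * t, 3 * hdim)
        self.wx.grad += self._x.reshape(b * t, self.n_in).T @ flat
        self.bx.grad += flat.sum(axis=0)
        return gx_all @ self.wx.value.T

    def params(self) -> list[Param]:
        return [self.wx, self.wh, self.bx, self.bh]


class GRUStack(Layer):
    """Three stacked GRU layers; forward returns the top layer's final hidden
    state (B, H)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 n_layers: int = 3) -> None:
        if n_layers < 1:
            raise ConfigurationError("GRU stack needs at least one layer")
        dims = [n_in] + [hidden] * n_layers
        self.layers = [GRU(dims[i], dims[i + 1], rng) for i in range(n_layers)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._t = x.shape[1]
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, -1]

    def backward(self, g_last: np.ndarray) -> np.ndarray:
        g = np.zeros((g_last.shape[0], self._t, g_last.shape[1]))
        g[:, -1] = g_last
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


# ---------------------------------------------------------------------------
# losses and optimizer


def softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    b = logits.shape[0]
    p = softmax(logits)
    ll = np.log(p[np.arange(b), targets] + 1e-300)
    grad = p.copy()
    grad[np.arange(b), targets] -= 1.0
    return float(-ll.mean()), grad / b


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


class Adam:
    """Adam with bias correction; operates in place on a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
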