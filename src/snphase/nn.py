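"""Minimal neural-network primitives used by the two genotyping models.

Implements exactly what the models need — dense layers, (bidirectional)
LSTM layers, label-smoothed softmax cross-entropy, Adam and the Lookahead
wrapper — as plain numpy with hand-derived backpropagation.  Every layer's
gradients are validated against central finite differences in the test
suite.  All randomness flows through an explicit ``numpy.random.Generator``
so training is deterministic under a fixed seed.

Layers compute in float32 by default (float64 is available for gradient
checking).  The LSTM keeps its three sigmoid gates in one contiguous block
(order i, f, o, then the tanh candidate g) so each time step costs two
matmuls and a handful of fused elementwise passes.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable via tanh; one vectorised pass
    return 0.5 * np.tanh(0.5 * x) + 0.5


def sigmoid(x: np.ndarray) -> np.ndarray:
    return _sigmoid(np.asarray(x))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base: a layer owns named parameters and matching gradient buffers."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0

    def param_items(self, prefix: str) -> List[Tuple[str, np.ndarray, np.ndarray]]:
        return [(f"{prefix}.{k}", self.params[k], self.grads[k])
                for k in sorted(self.params)]


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 scale: Optional[float] = None,
                 dtype: np.dtype = np.float32) -> None:
        super().__init__()
        if scale is None:
            scale = np.sqrt(2.0 / (d_in + d_out))
        self.params = {"W": rng.normal(0.0, scale, size=(d_in, d_out)).astype(dtype),
                       "b": np.zeros(d_out, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class LSTM(Layer):
    """Single-direction LSTM over (batch, time, features).

    Gate weight layout along the last axis: [i | f | o | g] with the first
    three sigmoid-activated and g tanh-activated.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 dtype: np.dtype = np.float32) -> None:
        super().__init__()
        self.hidden = hidden
        self.dtype = dtype
        k = 1.0 / np.sqrt(hidden)
        self.params = {
            "Wx": rng.uniform(-k, k, size=(d_in, 4 * hidden)).astype(dtype),
            "Wh": rng.uniform(-k, k, size=(hidden, 4 * hidden)).astype(dtype),
            "b": np.zeros(4 * hidden, dtype=dtype),
        }
        self.params["b"][hidden:2 * hidden] = 1.0   # forget-gate bias
        self.grads = {kk: np.zeros_like(v) for kk, v in self.params.items()}
        self._cache: Optional[tuple] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, T + 1, H), dtype=self.dtype)
        c = np.zeros((B, T + 1, H), dtype=self.dtype)
        gsig = np.zeros((B, T, 3 * H), dtype=self.dtype)   # i, f, o
        gg = np.zeros((B, T, H), dtype=self.dtype)
        tc = np.zeros((B, T, H), dtype=self.dtype)
        xW = x @ Wx                                  # one big matmul up front
        for t in range(T):
            z = xW[:, t] + h[:, t] @ Wh + b
            s = gsig[:, t]
            s[...] = _sigmoid(z[:, :3 * H])
            g = gg[:, t]
            g[...] = np.tanh(z[:, 3 * H:])
            gi, gf, go = s[:, :H], s[:, H:2 * H], s[:, 2 * H:]
            c[:, t + 1] = gf * c[:, t] + gi * g
            tc[:, t] = np.tanh(c[:, t + 1])
            h[:, t + 1] = go * tc[:, t]
        self._cache = (x, h, c, gsig, gg, tc)
        return h[:, 1:]

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x, h, c, gsig, gg, tc = self._cache
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dz_all = np.zeros((B, T, 4 * H), dtype=self.dtype)
        dh_next = np.zeros((B, H), dtype=self.dtype)
        dc_next = np.zeros((B, H), dtype=self.dtype)
        for t in range(T - 1, -1, -1):
            s = gsig[:, t]
            gi, gf, go = s[:, :H], s[:, H:2 * H], s[:, 2 * H:]
            g = gg[:, t]
            dh = dh_out[:, t] + dh_next
            do = dh * tc[:, t]
            dc = dc_next + dh * go * (1.0 - tc[:, t] ** 2)
            dc_next = dc * gf
            dz = dz_all[:, t]
            dz[:, :H] = (dc * g) * gi * (1.0 - gi)            # d i
            dz[:, H:2 * H] = (dc * c[:, t]) * gf * (1.0 - gf)  # d f
            dz[:, 2 * H:3 * H] = do * go * (1.0 - go)          # d o
            dz[:, 3 * H:] = (dc * gi) * (1.0 - g ** 2)         # d g
            dh_next = dz @ Wh.T
        # batched weight gradients over all time steps
        BT = B * T
        x2 = x.reshape(BT, -1)
        dz2 = dz_all.reshape(BT, 4 * H)
        self.grads["Wx"] += x2.T @ dz2
        self.grads["Wh"] += h[:, :-1].reshape(BT, H).T @ dz2
        self.grads["b"] += dz2.sum(axis=0)
        return (dz2 @ Wx.T).reshape(B, T, -1)


class BiLSTM(Layer):
    """Bidirectional LSTM; output concatenates the two directions (2H)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 dtype: np.dtype = np.float32) -> None:
        super().__init__()
        self.fwd = LSTM(d_in, hidden, rng, dtype=dtype)
        self.bwd = LSTM(d_in, hidden, rng, dtype=dtype)
        self.hidden = hidden

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dh: np.ndarray) -> np.ndarray:
        H = self.hidden
        dxf = self.fwd.backward(np.ascontiguousarray(dh[:, :, :H]))
        dxb = self.bwd.backward(np.ascontiguousarray(dh[:, ::-1, H:]))[:, ::-1]
        return dxf + dxb

    def zero_grad(self) -> None:
        self.fwd.zero_grad()
        self.bwd.zero_grad()

    def param_items(self, prefix: str):
        return (self.fwd.param_items(f"{prefix}.fwd")
                + self.bwd.param_items(f"{prefix}.bwd"))


def smoothed_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           smoothing: float = 0.1
                           ) -> Tuple[float, np.ndarray]:
    """Label-smoothed softmax CE, averaged over the batch.

    Returns the loss and d loss / d logits.
    """
    B, K = logits.shape
    p = softmax(np.asarray(logits, dtype=np.float64))
    logp = np.log(np.clip(p, 1e-12, None))
    target = np.full((B, K), smoothing / K)
    target[np.arange(B), labels] += 1.0 - smoothing
    loss = float(-(target * logp).sum() / B)
    dlogits = ((p - target) / B).astype(logits.dtype)
    return loss, dlogits


class Adam:
    def __init__(self, items: Sequence[Tuple[str, np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.items = list(items)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p, dtype=np.float64) for _, p, _ in self.items]
        self.v = [np.zeros_like(p, dtype=np.float64) for _, p, _ in self.items]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for i, (_, p, g) in enumerate(self.items):
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * (g * g)
            p -= (self.lr * (self.m[i] / b1c)
                  / (np.sqrt(self.v[i] / b2c) + self.eps)).astype(p.dtype)


class Lookahead:
    """Slow/fast weight averaging wrapper around an inner optimizer."""

    def __init__(self, inner: Adam, k: int = 5, alpha: float = 0.5) -> None:
        self.inner = inner
        self.k = k
        self.alpha = alpha
        self.counter = 0
        self.slow = [p.copy() for _, p, _ in inner.items]

    def step(self) -> None:
        self.inner.step()
        self.counter += 1
        if self.counter % self.k == 0:
            for s, (_, p, _) in zip(self.slow, self.inner.items):
                s += (self.alpha * (p - s)).astype(s.dtype)
                p[...] = s
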