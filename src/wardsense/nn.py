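"""Minimal numpy neural-network core for the sequence models.

Implements exactly the layers the symptom-prediction architecture
needs — temporal 1D convolution, max pooling, a GRU, dense layers,
dropout — with explicit backward passes and an Adam optimizer. The
forward/backward pairs are validated against numerical differentiation
in the test suite. Everything is deterministic given a
``numpy.random.Generator``.

Shapes follow the convention: convolution operates on ``(B, C, T)``,
the GRU on ``(B, T, I)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    if len(shape) == 3:  # conv kernels (C_out, C_in, K): fans over C_in*K
        fan_in = shape[1] * shape[2]
        fan_out = shape[0] * shape[2]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: parameters and their gradients are parallel dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv1d(Layer):
    """Temporal convolution with 'same' zero padding, stride 1.

    Input ``(B, C_in, T)`` -> output ``(B, C_out, T)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        self.params = {"W": glorot(rng, c_out, c_in, kernel),
                       "b": np.zeros(c_out)}
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = sliding_window_view(xp, self.kernel, axis=2)  # (B, C_in, T, K)
        self._cols = cols
        self._xshape = x.shape
        return np.einsum("bctk,ock->bot", cols, self.params["W"],
                         optimize=True) + self.params["b"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        self.grads["W"] += np.einsum("bctk,bot->ock", self._cols, dy, optimize=True)
        self.grads["b"] += dy.sum(axis=(0, 2))
        B, C, T = self._xshape
        p = self.kernel // 2
        dcols = np.einsum("bot,ock->bctk", dy, W, optimize=True)
        dxp = np.zeros((B, C, T + 2 * p))
        for k in range(self.kernel):
            dxp[:, :, k:k + T] += dcols[:, :, :, k]
        return dxp[:, :, p:p + T]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling along time; trailing remainder dropped."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, T = x.shape
        t_out = T // self.pool
        xr = x[:, :, :t_out * self.pool].reshape(B, C, t_out, self.pool)
        self._argmax = xr.argmax(axis=3)
        self._inshape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, T = self._inshape
        t_out = dy.shape[2]
        dxr = np.zeros((B, C, t_out, self.pool))
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=3)
        dx = np.zeros((B, C, T))
        dx[:, :, :t_out * self.pool] = dxr.reshape(B, C, t_out * self.pool)
        return dx


class Dropout(Layer):
    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = p

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None,
                train: bool = False) -> np.ndarray:
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class GRU(Layer):
    """Single-layer GRU; returns the last hidden state.

    Gate equations match the standard formulation
    (reset gate applied to the hidden branch of the candidate):
    ``z=σ(xWz+hUz+bz); r=σ(xWr+hUr+br);
    n=tanh(xWn+bn + r*(hUn+bhn)); h'=(1−z)n+zh``.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.hidden = hidden
        p = {}
        for g in ("z", "r", "n"):
            p[f"W{g}"] = glorot(rng, n_in, hidden)
            p[f"U{g}"] = glorot(rng, hidden, hidden)
            p[f"b{g}"] = np.zeros(hidden)
        p["bhn"] = np.zeros(hidden)
        self.params = p
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        p = self.params
        h = np.zeros((B, self.hidden))
        cache = []
        for t in range(T):
            xt = x[:, t, :]
            z = _sigmoid(xt @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(xt @ p["Wr"] + h @ p["Ur"] + p["br"])
            hUn = h @ p["Un"] + p["bhn"]
            n = np.tanh(xt @ p["Wn"] + p["bn"] + r * hUn)
            h_new = (1.0 - z) * n + z * h
            cache.append((xt, h, z, r, n, hUn))
            h = h_new
        self._cache = cache
        self._xshape = x.shape
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        p, g = self.params, self.grads
        B, T, _ = self._xshape
        dx = np.zeros(self._xshape)
        for t in range(T - 1, -1, -1):
            xt, h_prev, z, r, n, hUn = self._cache[t]
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dn_pre = dn * (1.0 - n ** 2)
            dr = dn_pre * hUn
            dhUn = dn_pre * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            g["Wn"] += xt.T @ dn_pre
            g["bn"] += dn_pre.sum(axis=0)
            g["Un"] += h_prev.T @ dhUn
            g["bhn"] += dhUn.sum(axis=0)
            g["Wz"] += xt.T @ dz_pre
            g["bz"] += dz_pre.sum(axis=0)
            g["Uz"] += h_prev.T @ dz_pre
            g["Wr"] += xt.T @ dr_pre
            g["br"] += dr_pre.sum(axis=0)
            g["Ur"] += h_prev.T @ dr_pre
            dx[:, t, :] = dz_pre @ p["Wz"].T + dr_pre @ p["Wr"].T + dn_pre @ p["Wn"].T
            dh = dh_prev + dhUn @ p["Un"].T + dz_pre @ p["Uz"].T + dr_pre @ p["Ur"].T
        return dx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {"W": glorot(rng, n_in, n_out), "b": np.zeros(n_out)}
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Adam:
    """Adam optimizer over a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.layers = layers
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, lay in enumerate(self.layers):
            for k, w in lay.params.items():
                grad = lay.grads[k]
                self.m[i][k] = b1 * self.m[i][k] + (1 - b1) * grad
                self.v[i][k] = b2 * self.v[i][k] + (1 - b2) * grad ** 2
                mhat = self.m[i][k] / (1 - b1 ** self.t)
                vhat = self.v[i][k] / (1 - b2 ** self.t)
                w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for lay in self.layers:
            lay.zero_grad()


# ---------------------------------------------------------------------------
# losses (masked, with analytic gradients on the pre-activation outputs)
# ---------------------------------------------------------------------------

def bce_with_logits(z: np.ndarray, y: np.ndarray, mask: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over ``mask`` entries; gradient w.r.t.
    the logits. Returns (loss, dz)."""
    n = int(mask.sum())
    if n == 0:
        return 0.0, np.zeros_like(z)
    ls = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = float((ls * mask).sum() / n)
    dz = (_sigmoid(z) - y) * mask / n
    return loss, dz


def mse(pred: np.ndarray, y: np.ndarray, mask: np.ndarray
        ) -> tuple[float, np.ndarray]:
    """Mean squared error over ``mask`` entries; gradient w.r.t. pred."""
    n = int(mask.sum())
    if n == 0:
        return 0.0, np.zeros_like(pred)
    d = (pred - y) * mask
    loss = float((d ** 2).sum() / n)
    return loss, 2.0 * d / n


class SeqNet:
    """The shared backbone: temporal conv blocks -> GRU -> FC -> heads.

    Input ``(B, 672, 31)``; each head emits one pre-activation scalar
    per example (a logit for deterioration heads, a unit-interval score
    for score heads). All heads share every parameter up to the final
    per-head dense layer — the multitask weight sharing is a single
    object, not copies.
    """

    def __init__(self, n_features: int, head_names: list[str],
                 conv_channels: tuple[int, ...] = (32, 64), kernel: int = 5,
                 pool: int = 2, gru_hidden: int = 64, dropout: float = 0.2,
                 head_width: int = 32, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.head_names = list(head_names)
        self.convs: list[tuple[Conv1d, ReLU, MaxPool1d]] = []
        c_prev = n_features
        for c in conv_channels:
            self.convs.append((Conv1d(c_prev, c, kernel, rng), ReLU(), MaxPool1d(pool)))
            c_prev = c
        self.gru = GRU(c_prev, gru_hidden, rng)
        self.drop = Dropout(dropout)
        self.fc = Dense(gru_hidden, head_width, rng)
        self.fc_act = ReLU()
        self.heads = {name: Dense(head_width, 1, rng) for name in head_names}
        self._init_seed = seed

    # -- plumbing ----------------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for conv, act, pl in self.convs:
            out.extend([conv, act, pl])
        out.extend([self.gru, self.drop, self.fc, self.fc_act])
        out.extend(self.heads.values())
        return out

    @property
    def param_layers(self) -> list[Layer]:
        return [lay for lay in self.layers if lay.params]

    def n_parameters(self) -> int:
        return sum(v.size for lay in self.param_layers for v in lay.params.values())

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
        h = np.transpose(x, (0, 2, 1))          # (B, C=31, T)
        for conv, act, pl in self.convs:
            h = pl.forward(act.forward(conv.forward(h)))
        h = np.transpose(h, (0, 2, 1))          # (B, T', C)
        h = self.gru.forward(h)
        h = self.drop.forward(h, rng=rng, train=train)
        h = self.fc_act.forward(self.fc.forward(h))
        self._fc_out = h
        return {name: self.heads[name].forward(h)[:, 0] for name in self.head_names}

    def backward(self, dheads: dict[str, np.ndarray]) -> None:
        dh = np.zeros_like(self._fc_out)
        for name, d in dheads.items():
            dh += self.heads[name].backward(d[:, None])
        dh = self.fc.backward(self.fc_act.backward(dh))
        dh = self.drop.backward(dh)
        dh = self.gru.backward(dh)
        dh = np.transpose(dh, (0, 2, 1))
        for conv, act, pl in reversed(self.convs):
            dh = conv.backward(act.backward(pl.backward(dh)))

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, lay in enumerate(self.param_layers):
            for k, v in lay.params.items():
                out[f"layer{i}.{k}"] = v.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, lay in enumerate(self.param_layers):
            for k in lay.params:
                lay.params[k] = state[f"layer{i}.{k}"].copy()
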