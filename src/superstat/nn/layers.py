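"""Layers and optimizer for the recurrent posterior approximator."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, stack

__all__ = ["Dense", "MLP", "LSTM", "Adam"]


class Module:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint weight shape mismatch")
            p.data = a.astype(np.float32)


class Dense(Module):
    """Affine layer ``x @ W + b`` with optional activation."""

    def __init__(self, n_in: int, n_out: int, activation: str | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor.param(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Tensor.param(np.zeros(n_out))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W + self.b
        if self.activation == "tanh":
            out = out.tanh()
        elif self.activation == "relu":
            out = out.relu()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return out

    def parameters(self):
        return [self.W, self.b]


class MLP(Module):
    """Feed-forward stack; hidden layers use tanh, output is linear."""

    def __init__(self, sizes: list[int], rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.layers = [
            Dense(a, b, activation="tanh" if i < len(sizes) - 2 else None, rng=rng)
            for i, (a, b) in enumerate(zip(sizes, sizes[1:]))
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    # numpy-only forward used when sampling (no tape needed)
    def forward_np(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(np.float32)
        for i, layer in enumerate(self.layers):
            x = x @ layer.W.data + layer.b.data
            if i < len(self.layers) - 1:
                x = np.tanh(x)
        return x


class LSTM(Module):
    """Single-layer LSTM consuming a (B, T, F) sequence.

    Returns the full hidden-state sequence (B, T, H): state t is a function
    of x_{1:t} only, so row t summarizes the observable history up to t.
    Forget-gate bias initialized to 1.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        k = math.sqrt(1.0 / hidden)
        self.W = Tensor.param(rng.uniform(-k, k, size=(n_in, 4 * hidden)))
        self.U = Tensor.param(rng.uniform(-k, k, size=(hidden, 4 * hidden)))
        b = np.zeros(4 * hidden, dtype=np.float32)
        b[hidden:2 * hidden] = 1.0
        self.b = Tensor.param(b)

    def parameters(self):
        return [self.W, self.U, self.b]

    def __call__(self, x: np.ndarray) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H), dtype=np.float32))
        c = Tensor(np.zeros((B, H), dtype=np.float32))
        hs: list[Tensor] = []
        sl = slice(None)
        for t in range(T):
            z = Tensor(x[:, t, :]) @ self.W + h @ self.U + self.b
            i = z[sl, 0:H].sigmoid()
            f = z[sl, H:2 * H].sigmoid()
            g = z[sl, 2 * H:3 * H].tanh()
            o = z[sl, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h)
        return stack(hs, axis=1)

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        """Tape-free forward pass for amortized inference."""
        B, T, _ = x.shape
        H = self.hidden
        W, U, b = self.W.data, self.U.data, self.b.data
        h = np.zeros((B, H), dtype=np.float32)
        c = np.zeros((B, H), dtype=np.float32)
        out = np.empty((B, T, H), dtype=np.float32)
        xp = x.astype(np.float32) @ W  # precompute input projections
        for t in range(T):
            z = xp[:, t, :] + h @ U + b
            i = 1.0 / (1.0 + np.exp(-z[:, 0:H]))
            f = 1.0 / (1.0 + np.exp(-z[:, H:2 * H]))
            g = np.tanh(z[:, 2 * H:3 * H])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * H:4 * H]))
            c = f * c + i * g
            h = o * np.tanh(c)
            out[:, t, :] = h
        return out


class Adam:
    """Adam with global-norm gradient clipping and cosine learning-rate decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float = 5.0, total_steps: int | None = None):
        self.params = params
        self.lr0 = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.total_steps = total_steps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def _lr(self) -> float:
        if not self.total_steps:
            return self.lr0
        frac = min(self.t / self.total_steps, 1.0)
        return self.lr0 * 0.5 * (1.0 + math.cos(math.pi * frac))

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm:
            total = math.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = np.float32(self.clip_norm / (total + 1e-12))
                grads = [g * scale for g in grads]
        lr = self._lr()
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= np.float32(lr) * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
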