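"""Conditional posterior heads: full-covariance Gaussian and coupling flow.

Both heads map a conditioning vector (summary state, optionally concatenated
with already-sampled parameters) to a distribution over a parameter block on
the standardized, unconstrained scale.  ``log_prob`` builds the training
graph; ``sample`` is a tape-free numpy path used during amortized inference.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat
from .layers import MLP, Module

__all__ = ["ConditionalGaussianHead", "CouplingFlowHead"]

_LOG2PI = math.log(2.0 * math.pi)
_LD_CAP = 5.0  # bound on log precision-diagonal entries
_S_CAP = 3.0  # bound on coupling log-scales


class ConditionalGaussianHead(Module):
    """Multivariate Gaussian with predicted mean and Cholesky precision factor.

    The conditioner outputs a mean, the log-diagonal and the strictly-lower
    entries of a lower-triangular matrix A with positive diagonal such that
    ``z = A (y - mu)`` is standard normal, i.e. A is the inverse Cholesky
    factor of the covariance.  This keeps the log-density free of matrix
    inversions: ``log q = sum(log diag A) - ||z||^2 / 2 - d/2 log(2 pi)``.
    """

    kind = "gaussian"

    def __init__(self, dim: int, cond_dim: int, hidden: tuple[int, ...] = (64, 64),
                 rng: np.random.Generator | None = None):
        self.dim = dim
        self.cond_dim = cond_dim
        n_out = 2 * dim + dim * (dim - 1) // 2
        self.net = MLP([cond_dim, *hidden, n_out], rng=rng)
        # damp the output layer so the head starts near N(0, I)
        self.net.layers[-1].W.data *= 0.01
        self._pairs = [(i, j) for i in range(dim) for j in range(i)]

    def parameters(self):
        return self.net.parameters()

    def _split_np(self, out: np.ndarray):
        d = self.dim
        mu = out[:, :d]
        ld = _LD_CAP * np.tanh(out[:, d:2 * d] / _LD_CAP)
        off = out[:, 2 * d:]
        return mu, ld, off

    def log_prob(self, y: np.ndarray, cond: Tensor) -> Tensor:
        """Log-density of targets ``y`` (N, d) given conditions; returns (N,)."""
        d = self.dim
        out = self.net(cond)
        mu = out[:, 0:d]
        ld = (out[:, d:2 * d] * (1.0 / _LD_CAP)).tanh() * _LD_CAP
        r = Tensor(y) - mu
        diag = ld.exp()
        z_cols = []
        for i in range(d):
            zi = diag[:, i:i + 1] * r[:, i:i + 1]
            for idx, (ii, jj) in enumerate(self._pairs):
                if ii == i:
                    col = 2 * d + idx
                    zi = zi + out[:, col:col + 1] * r[:, jj:jj + 1]
            z_cols.append(zi)
        z = concat(z_cols, axis=1)
        return ld.sum(axis=1) - 0.5 * z.square().sum(axis=1) - 0.5 * d * _LOG2PI

    def sample(self, cond: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One draw per condition row (vectorized over rows)."""
        d = self.dim
        out = self.net.forward_np(cond)
        mu, ld, off = self._split_np(out)
        diag = np.exp(ld)
        eps = rng.standard_normal(mu.shape).astype(np.float32)
        y = np.empty_like(mu)
        for i in range(d):
            acc = eps[:, i].copy()
            for idx, (ii, jj) in enumerate(self._pairs):
                if ii == i:
                    acc -= off[:, idx] * y[:, jj]
            y[:, i] = acc / diag[:, i]
        return mu + y

    def moments(self, cond: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predicted mean and marginal SDs (via the implied covariance)."""
        d = self.dim
        out = self.net.forward_np(cond)
        mu, ld, off = self._split_np(out)
        A = np.zeros((len(mu), d, d), dtype=np.float32)
        A[:, np.arange(d), np.arange(d)] = np.exp(ld)
        for idx, (i, j) in enumerate(self._pairs):
            A[:, i, j] = off[:, idx]
        Ainv = np.linalg.inv(A)
        cov = Ainv @ np.swapaxes(Ainv, 1, 2)
        return mu, np.sqrt(np.maximum(cov[:, np.arange(d), np.arange(d)], 0.0))


class CouplingFlowHead(Module):
    """Conditional normalizing flow built from affine coupling blocks.

    Each block splits the vector into two halves by an alternating mask,
    predicts a bounded log-scale ``s`` and shift ``t`` for one half from the
    other half plus the conditioning vector, and applies
    ``y_b = x_b * exp(s) + t``.  The base distribution is standard normal.
    """

    kind = "flow"

    def __init__(self, dim: int, cond_dim: int, n_blocks: int = 4,
                 hidden: tuple[int, ...] = (64,),
                 rng: np.random.Generator | None = None):
        if dim < 2:
            raise ValueError("coupling flow needs dim >= 2 (use the gaussian head)")
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.cond_dim = cond_dim
        self.n_blocks = n_blocks
        self.masks = []
        self.nets = []
        for b in range(n_blocks):
            keep = np.arange(dim)[(np.arange(dim) + b) % 2 == 0]
            move = np.arange(dim)[(np.arange(dim) + b) % 2 == 1]
            self.masks.append((keep, move))
            net = MLP([len(keep) + cond_dim, *hidden, 2 * len(move)], rng=rng)
            net.layers[-1].W.data *= 0.01
            self.nets.append(net)

    def parameters(self):
        return [p for net in self.nets for p in net.parameters()]

    def _st(self, net: MLP, a: Tensor, cond: Tensor, n_move: int):
        out = net(concat([a, cond], axis=1))
        s = (out[:, 0:n_move] * (1.0 / _S_CAP)).tanh() * _S_CAP
        t = out[:, n_move:2 * n_move]
        return s, t

    def log_prob(self, y: np.ndarray, cond: Tensor) -> Tensor:
        """Inverse pass y -> z with log|det| accumulation; returns (N,)."""
        d = self.dim
        x = Tensor(y.astype(np.float32))
        logdet = Tensor(np.zeros(len(y), dtype=np.float32))
        sl = slice(None)
        for b in reversed(range(self.n_blocks)):
            keep, move = self.masks[b]
            a = x[sl, keep]
            s, t = self._st(self.nets[b], a, cond, len(move))
            zb = (x[sl, move] - t) * (-s).exp()
            logdet = logdet + (-s).sum(axis=1)
            perm = np.argsort(np.concatenate([keep, move]))
            x = concat([a, zb], axis=1)[sl, perm]
        return logdet - 0.5 * x.square().sum(axis=1) - 0.5 * d * _LOG2PI

    def _st_np(self, net: MLP, a: np.ndarray, cond: np.ndarray, n_move: int):
        out = net.forward_np(np.concatenate([a, cond], axis=1))
        s = _S_CAP * np.tanh(out[:, :n_move] / _S_CAP)
        t = out[:, n_move:]
        return s, t

    def forward_np(self, z: np.ndarray, cond: np.ndarray) -> np.ndarray:
        """Generative direction z -> y (numpy only)."""
        x = z.astype(np.float32).copy()
        for b in range(self.n_blocks):
            keep, move = self.masks[b]
            s, t = self._st_np(self.nets[b], x[:, keep], cond, len(move))
            x[:, move] = x[:, move] * np.exp(s) + t
        return x

    def inverse_np(self, y: np.ndarray, cond: np.ndarray) -> np.ndarray:
        x = y.astype(np.float32).copy()
        for b in reversed(range(self.n_blocks)):
            keep, move = self.masks[b]
            s, t = self._st_np(self.nets[b], x[:, keep], cond, len(move))
            x[:, move] = (x[:, move] - t) * np.exp(-s)
        return x

    def sample(self, cond: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((len(cond), self.dim)).astype(np.float32)
        return self.forward_np(z, cond)

    def moments(self, cond: np.ndarray, n: int = 256,
                rng: np.random.Generator | None = None):
        """Monte-Carlo mean/SD (the flow has no closed-form moments)."""
        rng = rng or np.random.default_rng(0)
        draws = np.stack([self.sample(cond, rng) for _ in range(n)])
        return draws.mean(axis=0), draws.std(axis=0)
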