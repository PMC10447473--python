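"""Amortized neural Bayesian filtering for superstatistical models.

The approximator pairs a recurrent summary network — a single LSTM layer
whose hidden state ``h_t`` summarizes the observed prefix ``x_{1:t}`` — with
conditional generative heads that approximate the joint filtering posterior
``q(theta_t, eta | h_t)`` in its ancestral factorization: the static
high-level parameters are drawn from ``q(eta | h_t)`` first, then the
current low-level parameters from ``q(theta_t | h_t, eta)``.

Training minimizes the expected negative log posterior density of the true
simulated parameters, summed over all time steps,

    E_{(eta, theta_{0:T}, x_{1:T})} [ - sum_t log q(theta_t, eta | x_{1:t}) ],

estimated over batches of simulator output.  Because the per-step term only
conditions on the prefix ``x_{1:t}``, a network trained on sequences of
length T is simultaneously trained for every shorter series.

All parameters are learned on an unconstrained, standardized scale: strictly
positive components are log-transformed and all targets are z-scored with
constants estimated from a pilot simulation and frozen into the checkpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .models import ModelSpec, ObservationSeries, SimulationRecord, simulate_dataset
from .nn import LSTM, Adam, ConditionalGaussianHead, CouplingFlowHead, Tensor, concat

__all__ = ["TrainingConfig", "FilterPosterior", "AmortizedFilter", "load_checkpoint"]


@dataclass
class TrainingConfig:
    """Training settings for the amortized filter."""

    n_sim: int = 2048  # simulation budget (records)
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 3e-3
    seed: int = 0
    T: int = 110  # training sequence length
    mode: str = "offline"  # or "online"
    hidden: int = 64
    head: str = "gaussian"  # or "flow" (theta head; eta head is gaussian)
    head_hidden: tuple[int, ...] = (64, 64)
    flow_blocks: int = 4
    n_pilot: int = 1000
    clip_norm: float = 5.0
    t_subsample: int = 0  # if >0, train on this many random t per sequence

    def __post_init__(self) -> None:
        if self.mode not in ("offline", "online"):
            raise ValueError("mode must be 'offline' or 'online'")
        if self.head not in ("gaussian", "flow"):
            raise ValueError("head must be 'gaussian' or 'flow'")


@dataclass
class FilterPosterior:
    """Per-time-step joint posterior draws of (theta_t, eta), natural scale.

    ``theta`` has shape (T, n, d) and ``eta`` (T, n, k); draw j at step t is
    a joint draw (eta then theta_t given eta).
    """

    theta: np.ndarray
    eta: np.ndarray
    theta_names: tuple[str, ...]
    eta_names: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def theta_mean(self) -> np.ndarray:
        return self.theta.mean(axis=1)

    def theta_sd(self) -> np.ndarray:
        return self.theta.std(axis=1)

    def eta_mean(self) -> np.ndarray:
        return self.eta.mean(axis=1)

    def eta_sd(self) -> np.ndarray:
        return self.eta.std(axis=1)

    def to_frame(self):
        """Long-format draws table: t, draw, parameter, value (t 1-based)."""
        import pandas as pd

        T, n, d = self.theta.shape
        frames = []
        for names, arr in ((self.theta_names, self.theta), (self.eta_names, self.eta)):
            for j, name in enumerate(names):
                frames.append(pd.DataFrame({
                    "t": np.repeat(np.arange(1, T + 1), n),
                    "draw": np.tile(np.arange(n), T),
                    "parameter": name,
                    "value": arr[:, :, j].ravel(),
                }))
        return pd.concat(frames, ignore_index=True)


_RT_MIN_WINDOW = 20  # trials; rolling-minimum window for the encoder


def _ddm_features(rt: np.ndarray, choice: np.ndarray, condition: np.ndarray,
                  n_conditions: int) -> np.ndarray:
    """Per-step numeric encoding of a DDM series (causal in t).

    Besides the current trial's (log rt, rt, signed choice), two causal
    prefix statistics of the response times are supplied: the expanding
    minimum and a rolling minimum over the last few trials.  The minimum rt
    is the near-sufficient statistic for the non-decision time, a quantity a
    plain recurrent layer is slow to learn from raw trials.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    rt = np.asarray(rt, dtype=np.float32)
    cummin = np.minimum.accumulate(rt)
    w = _RT_MIN_WINDOW
    if len(rt) > w:
        roll = np.empty_like(rt)
        roll[:w] = cummin[:w]
        roll[w - 1:] = sliding_window_view(rt, w).min(axis=1)
    else:
        roll = cummin
    cols = [np.log(rt), rt, 2.0 * choice - 1.0, cummin, roll]
    if n_conditions > 1:
        cols.append(np.eye(n_conditions, dtype=np.float32)[condition])
    return np.column_stack(cols).astype(np.float32)


def _eta_transforms(model: ModelSpec) -> list[str]:
    out = []
    for name in model.transition.eta_names:
        lo, _ = model.transition.eta_priors[name].support
        out.append("log" if lo >= 0 else "identity")
    return out


class AmortizedFilter:
    """Recurrent summary network + posterior heads for one generative model."""

    def __init__(self, model: ModelSpec, config: TrainingConfig | None = None):
        self.model = model
        self.config = config or TrainingConfig()
        self.d_theta = model.low.dim
        self.d_eta = model.transition.eta_dim
        self.eta_tf = _eta_transforms(model)
        rng = np.random.default_rng(self.config.seed)
        n_feat = self._n_features()
        self.summary = LSTM(n_feat, self.config.hidden, rng=rng)
        H = self.config.hidden
        hh = tuple(self.config.head_hidden)
        if self.d_eta:
            self.eta_head = ConditionalGaussianHead(self.d_eta, H, hidden=hh, rng=rng)
        else:
            self.eta_head = None
        cond_dim = H + self.d_eta
        if self.config.head == "flow" and self.d_theta >= 2:
            self.theta_head = CouplingFlowHead(
                self.d_theta, cond_dim, n_blocks=self.config.flow_blocks,
                hidden=hh[:1], rng=rng)
        else:
            self.theta_head = ConditionalGaussianHead(
                self.d_theta, cond_dim, hidden=hh, rng=rng)
        # standardization constants, set by fit_standardization
        self.feat_loc = np.zeros(n_feat, dtype=np.float32)
        self.feat_scale = np.ones(n_feat, dtype=np.float32)
        self.theta_loc = np.zeros(self.d_theta, dtype=np.float32)
        self.theta_scale = np.ones(self.d_theta, dtype=np.float32)
        self.eta_loc = np.zeros(self.d_eta, dtype=np.float32)
        self.eta_scale = np.ones(self.d_eta, dtype=np.float32)
        self.history: list[float] = []
        self.trained = False

    # ------------------------------------------------------------------
    # encodings
    # ------------------------------------------------------------------
    def _n_features(self) -> int:
        if self.model.low.kind == "poisson":
            return 1
        C = self.model.low.n_conditions
        return 5 + (C if C > 1 else 0)

    def encode(self, series: ObservationSeries) -> np.ndarray:
        """Per-trial numeric features (T, F), standardized."""
        low = self.model.low
        if low.kind != series.kind:
            raise ValueError("series kind does not match the trained model")
        if series.kind == "poisson":
            if np.any(~np.isfinite(series.counts.astype(float))):
                raise ValueError("non-finite values in count series")
            feats = series.counts.astype(np.float32)[:, None]
        else:
            if np.any(~np.isfinite(series.rt)):
                raise ValueError("non-finite response times")
            feats = _ddm_features(series.rt, series.choice, series.condition,
                                  low.n_conditions)
        return (feats - self.feat_loc) / self.feat_scale

    def _theta_u(self, theta_nat: np.ndarray) -> np.ndarray:
        u = self.model.low.to_unconstrained(theta_nat)
        return ((u - self.theta_loc) / self.theta_scale).astype(np.float32)

    def _theta_nat(self, u_std: np.ndarray) -> np.ndarray:
        u = u_std.astype(np.float64) * self.theta_scale + self.theta_loc
        return self.model.low.to_natural(u)

    def _eta_u(self, eta_nat: np.ndarray) -> np.ndarray:
        u = np.array(eta_nat, dtype=float)
        for j, tf in enumerate(self.eta_tf):
            if tf == "log":
                u[..., j] = np.log(np.maximum(u[..., j], 1e-12))
        return ((u - self.eta_loc) / self.eta_scale).astype(np.float32)

    def _eta_nat(self, u_std: np.ndarray) -> np.ndarray:
        u = u_std.astype(np.float64) * self.eta_scale + self.eta_loc
        for j, tf in enumerate(self.eta_tf):
            if tf == "log":
                u[..., j] = np.exp(u[..., j])
        return u

    # ------------------------------------------------------------------
    # simulation-based training
    # ------------------------------------------------------------------
    def _simulate_batch(self, seeds: np.ndarray, T: int) -> list[SimulationRecord]:
        return [simulate_dataset(self.model, T, int(s)) for s in seeds]

    def fit_standardization(self, records: list[SimulationRecord]) -> None:
        """Estimate feature/target z-scoring constants; frozen afterwards."""
        low = self.model.low
        raw_feats = []
        for rec in records:
            s = rec.series
            if s.kind == "poisson":
                raw_feats.append(s.counts.astype(np.float32)[:, None])
            else:
                raw_feats.append(
                    _ddm_features(s.rt, s.choice, s.condition, low.n_conditions))
        feats = np.concatenate(raw_feats, axis=0)
        self.feat_loc = feats.mean(axis=0).astype(np.float32)
        self.feat_scale = np.maximum(feats.std(axis=0), 1e-3).astype(np.float32)
        thetas = np.concatenate([low.to_unconstrained(r.trajectory.values) for r in records])
        self.theta_loc = thetas.mean(axis=0).astype(np.float32)
        self.theta_scale = np.maximum(thetas.std(axis=0), 1e-3).astype(np.float32)
        if self.d_eta:
            self.eta_loc[:] = 0.0
            self.eta_scale[:] = 1.0
            etas_nat = np.stack([r.eta.values for r in records])
            etas_u = np.stack([self._eta_u(e) for e in etas_nat])
            self.eta_loc = etas_u.mean(axis=0).astype(np.float32)
            self.eta_scale = np.maximum(etas_u.std(axis=0), 1e-3).astype(np.float32)

    def parameters(self) -> list[Tensor]:
        ps = self.summary.parameters() + self.theta_head.parameters()
        if self.eta_head is not None:
            ps = self.eta_head.parameters() + ps
        return ps

    def loss(self, records: list[SimulationRecord]) -> Tensor:
        """Monte-Carlo training criterion for one batch (mean over records of
        the negative log posterior density summed over time steps)."""
        B = len(records)
        T = len(records[0].series)
        x = np.stack([self.encode(r.series) for r in records])
        theta_t = np.stack([self._theta_u(r.trajectory.values[1:]) for r in records])
        h = self.summary(x).reshape(B * T, self.config.hidden)
        total = None
        idx = None
        if self.config.t_subsample and self.config.t_subsample < T:
            # uniform random subset of time steps (memory relief; off by default)
            rng = np.random.default_rng((self.config.seed + 7919 * len(self.history)) % 2**31)
            tsel = rng.choice(T, size=self.config.t_subsample, replace=False)
            idx = (np.arange(B)[:, None] * T + tsel[None, :]).ravel()
            h = h[idx]
        y_theta = theta_t.reshape(B * T, self.d_theta)
        if idx is not None:
            y_theta = y_theta[idx]
        if self.eta_head is not None:
            eta_u = np.stack([self._eta_u(r.eta.values) for r in records])
            y_eta = np.repeat(eta_u, T, axis=0)
            if idx is not None:
                y_eta = y_eta[idx]
            lp_eta = self.eta_head.log_prob(y_eta, h)
            cond = concat([h, Tensor(y_eta)], axis=1)
            total = lp_eta.sum()
        else:
            cond = h
        lp_theta = self.theta_head.log_prob(y_theta, cond)
        total = lp_theta.sum() if total is None else total + lp_theta.sum()
        if not np.isfinite(total.data):
            raise FloatingPointError("non-finite log-density in training batch")
        return total * (-1.0 / B)

    def train(self, config: TrainingConfig | None = None,
              records: list[SimulationRecord] | None = None) -> list[float]:
        """Run simulation-based training; returns the per-epoch loss curve.

        ``records`` may supply a pre-computed offline store; otherwise the
        model's simulator is used (offline: one fixed set; online: fresh
        simulations every epoch).
        """
        if config is not None:
            self.config = config
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        T = cfg.T
        if records is None:
            seeds = rng.integers(0, 2**31 - 1, size=cfg.n_sim)
            records = self._simulate_batch(seeds, T)
        pilot = records[: min(cfg.n_pilot, len(records))]
        self.fit_standardization(pilot)
        n_batches = max(len(records) // cfg.batch_size, 1)
        opt = Adam(self.parameters(), lr=cfg.learning_rate,
                   clip_norm=cfg.clip_norm, total_steps=cfg.epochs * n_batches)
        self.history = []
        best: list[np.ndarray] | None = None
        for epoch in range(cfg.epochs):
            if cfg.mode == "online" and epoch > 0:
                seeds = rng.integers(0, 2**31 - 1, size=cfg.n_sim)
                records = self._simulate_batch(seeds, T)
            order = rng.permutation(len(records))
            epoch_loss = 0.0
            for b in range(n_batches):
                batch = [records[i] for i in order[b * cfg.batch_size:(b + 1) * cfg.batch_size]]
                if not batch:
                    continue
                try:
                    L = self.loss(batch)
                except FloatingPointError:
                    if best is not None:  # divergence: restore last good state
                        self._load_arrays(best)
                    raise
                L.backward()
                opt.step()
                opt.zero_grad()
                epoch_loss += float(L.data)
            self.history.append(epoch_loss / n_batches)
            best = [p.data.copy() for p in self.parameters()]
        self.trained = True
        return self.history

    def _load_arrays(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays):
            p.data = a.copy()

    # ------------------------------------------------------------------
    # amortized inference
    # ------------------------------------------------------------------
    def summarize(self, series: ObservationSeries) -> np.ndarray:
        """Hidden-state sequence (T, H); row t depends only on x_{1:t}."""
        x = self.encode(series)[None, :, :]
        return self.summary.forward_np(x)[0]

    def filter(self, series: ObservationSeries, n_draws: int = 1000,
               seed: int = 0, chunk: int = 200_000) -> FilterPosterior:
        """Joint filtering posterior draws for every prefix of the series."""
        T = len(series)
        if self.trained and T > self.config.T:
            import warnings

            warnings.warn(
                f"series length {T} exceeds training length {self.config.T}; "
                "the filter extrapolates")
        h = self.summarize(series)
        H = h.shape[1]
        rng = np.random.default_rng(seed)
        theta = np.empty((T, n_draws, self.d_theta))
        eta = np.empty((T, n_draws, self.d_eta))
        if n_draws == 0:
            return self._package(theta, eta, series)
        rows_per_t = max(chunk // max(n_draws, 1), 1)
        for start in range(0, T, rows_per_t):
            stop = min(start + rows_per_t, T)
            nt = stop - start
            cond = np.repeat(h[start:stop], n_draws, axis=0)  # (nt*n, H)
            if self.eta_head is not None:
                eta_u = self.eta_head.sample(cond, rng)
                cond_th = np.concatenate([cond, eta_u], axis=1)
                eta[start:stop] = self._eta_nat(eta_u).reshape(nt, n_draws, self.d_eta)
            else:
                cond_th = cond
            th_u = self.theta_head.sample(cond_th, rng)
            theta[start:stop] = self._theta_nat(th_u).reshape(nt, n_draws, self.d_theta)
        return self._package(theta, eta, series)

    def _package(self, theta, eta, series) -> FilterPosterior:
        return FilterPosterior(
            theta, eta,
            theta_names=self.model.low.param_names,
            eta_names=self.model.transition.eta_names,
            provenance={"model": self.model.name, "T": len(series),
                        "trained": self.trained},
        )

    # ------------------------------------------------------------------
    # checkpointing
    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"w{i}": p.data for i, p in enumerate(self.parameters())}
        arrays.update(
            feat_loc=self.feat_loc, feat_scale=self.feat_scale,
            theta_loc=self.theta_loc, theta_scale=self.theta_scale,
            eta_loc=self.eta_loc, eta_scale=self.eta_scale,
        )
        np.savez(path / "weights.npz", **arrays)
        cfg = asdict(self.config)
        cfg["head_hidden"] = list(self.config.head_hidden)
        meta = {
            "config": cfg,
            "model_name": self.model.name,
            "n_conditions": self.model.low.n_conditions,
            "eta_transforms": self.eta_tf,
            "history": self.history,
            "trained": self.trained,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path, model: ModelSpec) -> "AmortizedFilter":
        path = Path(path)
        if not (path / "weights.npz").exists():
            raise FileNotFoundError(f"no checkpoint at {path}")
        meta = json.loads((path / "meta.json").read_text())
        cfg_d = dict(meta["config"])
        cfg_d["head_hidden"] = tuple(cfg_d["head_hidden"])
        cfg = TrainingConfig(**cfg_d)
        if meta["model_name"] != model.name:
            raise ValueError(
                f"checkpoint was trained for model {meta['model_name']!r}, "
                f"got {model.name!r}")
        obj = cls(model, cfg)
        with np.load(path / "weights.npz") as z:
            obj._load_arrays([z[f"w{i}"] for i in range(len(obj.parameters()))])
            obj.feat_loc = z["feat_loc"]
            obj.feat_scale = z["feat_scale"]
            obj.theta_loc = z["theta_loc"]
            obj.theta_scale = z["theta_scale"]
            obj.eta_loc = z["eta_loc"]
            obj.eta_scale = z["eta_scale"]
        obj.history = list(meta.get("history", []))
        obj.trained = bool(meta.get("trained", True))
        return obj


def load_checkpoint(path: str | Path, model: ModelSpec) -> AmortizedFilter:
    """Convenience alias for :meth:`AmortizedFilter.load`."""
    return AmortizedFilter.load(path, model)
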