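"""Model-criticism toolbox for superstatistical models.

Implements the validation workflow used throughout the package:

- simulation-based calibration (SBC): ranks of true parameters among
  posterior draws across many simulated data sets must be uniform;
- recovery metrics: MAE-over-time and posterior-SD-over-time curves plus
  truth-vs-posterior-mean scatter at selected time points;
- retrodictive checks: re-simulating the observed span from per-step
  posterior draws;
- multi-horizon prediction: propagating joint (theta_t0, eta) posterior
  draws through the transition model to simulate future observations;
- maximum mean discrepancy (MMD) between two samples (unbiased U-statistic,
  Gaussian kernel, median-heuristic bandwidth);
- simple moving average (SMA) smoothing with prefix-mean edge handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import (
    HighLevelParams,
    ModelSpec,
    ObservationSeries,
    ParameterTrajectory,
    SimulationRecord,
    simulate_dataset,
    simulate_trajectory,
    _observe_ddm,
    _observe_poisson,
)

__all__ = [
    "SBCResult", "RecoveryReport", "PredictionBand",
    "sbc", "sbc_ranks_uniformity", "ecdf_band_violation",
    "recovery", "retrodictive_check", "multi_horizon_predict",
    "mmd", "sma", "band_coverage",
]


# ---------------------------------------------------------------------------
# simulation-based calibration
# ---------------------------------------------------------------------------


@dataclass
class SBCResult:
    """Ranks and uniformity diagnostics per (parameter, checkpoint t)."""

    ranks: dict  # (param, t) -> int array of length n_sim
    n_draws: int
    ks_stat: dict = field(default_factory=dict)
    ks_pvalue: dict = field(default_factory=dict)
    ecdf_violation: dict = field(default_factory=dict)  # fraction of grid outside band


def sbc_ranks_uniformity(ranks: np.ndarray, n_draws: int) -> tuple[float, float]:
    """KS test of rank uniformity (ranks take values in {0..n_draws})."""
    u = (np.asarray(ranks) + 0.5) / (n_draws + 1)
    res = stats.kstest(u, "uniform")
    return float(res.statistic), float(res.pvalue)


def ecdf_band_violation(ranks: np.ndarray, n_draws: int, level: float = 0.99,
                        n_mc: int = 2000, seed: int = 0) -> float:
    """Fraction of ECDF evaluation points outside a simultaneous MC band.

    The band is built by simulating ``n_mc`` rank sets of the same size from
    the uniform null and taking per-point quantiles of the ECDF calibrated so
    the *simultaneous* coverage is ``level``.
    """
    ranks = np.asarray(ranks)
    n = len(ranks)
    grid = np.arange(n_draws + 1)
    ecdf = np.searchsorted(np.sort(ranks), grid, side="right") / n
    rng = np.random.default_rng(seed)
    null = rng.integers(0, n_draws + 1, size=(n_mc, n))
    null_ecdf = (np.sort(null, axis=1)[:, None, :] <= grid[None, :, None]).mean(axis=2)
    # calibrate point-wise alpha to reach simultaneous coverage
    for alpha in np.linspace((1 - level) / 10, (1 - level), 25)[::-1]:
        lo = np.quantile(null_ecdf, alpha / 2, axis=0)
        hi = np.quantile(null_ecdf, 1 - alpha / 2, axis=0)
        inside = np.all((null_ecdf >= lo) & (null_ecdf <= hi), axis=1).mean()
        if inside >= level:
            break
    return float(np.mean((ecdf < lo) | (ecdf > hi)))


def sbc(
    model: ModelSpec,
    sampler,
    n_sim: int,
    n_draws: int,
    checkpoints: list[int],
    T: int,
    seed: int = 0,
    params: list[str] | None = None,
) -> SBCResult:
    """Simulation-based calibration of a posterior sampler.

    ``sampler(series, n_draws, seed) -> dict`` must return, for each
    checkpoint t in ``checkpoints``, an array of draws of shape (n_draws, d)
    keyed by t (draws of theta_t given x_{1:t}).  For every simulated record
    the rank of the true theta_t among the draws is recorded.
    """
    if n_sim < 100:
        warnings.warn("SBC with fewer than 100 simulations is underpowered")
    names = params or list(model.low.param_names)
    cols = [model.low.param_names.index(p) for p in names]
    ranks: dict = {(p, t): np.empty(n_sim, dtype=int) for p in names for t in checkpoints}
    ss = np.random.SeedSequence(seed)
    sim_seeds = ss.generate_state(n_sim) % (2**31 - 1)
    for i in range(n_sim):
        rec = simulate_dataset(model, T, int(sim_seeds[i]))
        draws = sampler(rec.series, n_draws, int(sim_seeds[i]) + 1)
        for t in checkpoints:
            th = rec.trajectory.values[t]
            for p, c in zip(names, cols):
                ranks[(p, t)][i] = int(np.sum(draws[t][:, c] < th[c]))
    res = SBCResult(ranks, n_draws)
    for key, r in ranks.items():
        s, pv = sbc_ranks_uniformity(r, n_draws)
        res.ks_stat[key] = s
        res.ks_pvalue[key] = pv
        res.ecdf_violation[key] = ecdf_band_violation(r, n_draws, seed=seed + 1)
    return res


# ---------------------------------------------------------------------------
# recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Per-parameter recovery curves and scatter diagnostics."""

    param_names: tuple[str, ...]
    mae: np.ndarray  # (T, d): median over records of |truth - post mean|
    sd: np.ndarray  # (T, d): median posterior SD
    sd_mad: np.ndarray  # (T, d): median absolute deviation of posterior SD
    scatter_t: dict = field(default_factory=dict)  # t -> (truths, means) arrays
    correlation: dict = field(default_factory=dict)  # (param, t) -> r


def recovery(
    records: list[SimulationRecord],
    posteriors: list,
    scatter_at: list[int] | None = None,
) -> RecoveryReport:
    """Aggregate recovery metrics across matched (truth, posterior) pairs."""
    if len(records) != len(posteriors):
        raise ValueError("records and posteriors must match one-to-one")
    T = posteriors[0].theta.shape[0]
    names = records[0].trajectory.names
    truths = np.stack([r.trajectory.values[1:T + 1] for r in records])  # (N, T, d)
    means = np.stack([p.theta_mean() for p in posteriors])
    sds = np.stack([p.theta_sd() for p in posteriors])
    if truths.shape != means.shape:
        raise ValueError("trajectory and posterior lengths differ")
    mae = np.median(np.abs(truths - means), axis=0)
    sd_med = np.median(sds, axis=0)
    sd_mad = np.median(np.abs(sds - sd_med[None]), axis=0)
    rep = RecoveryReport(names, mae, sd_med, sd_mad)
    for t in scatter_at or []:
        tr, mn = truths[:, t - 1, :], means[:, t - 1, :]
        rep.scatter_t[t] = (tr, mn)
        for j, p in enumerate(names):
            rep.correlation[(p, t)] = float(np.corrcoef(tr[:, j], mn[:, j])[0, 1])
    return rep


# ---------------------------------------------------------------------------
# predictive bands
# ---------------------------------------------------------------------------


@dataclass
class PredictionBand:
    """Per-step median and central 95% interval of simulated observables."""

    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    horizon_start: int = 0

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.median + 1e-12)
                and np.all(self.median <= self.upper + 1e-12)):
            raise ValueError("band quantiles are not ordered")

    def __len__(self) -> int:
        return len(self.median)


def _series_values(series: ObservationSeries) -> np.ndarray:
    return (series.counts if series.kind == "poisson" else series.rt).astype(float)


def _summarize(sims: np.ndarray, horizon_start: int = 0,
               sma_period: int = 0) -> PredictionBand:
    if sma_period > 1:
        sims = np.stack([sma(s, sma_period) for s in sims])
    med = np.median(sims, axis=0)
    lo = np.quantile(sims, 0.025, axis=0)
    hi = np.quantile(sims, 0.975, axis=0)
    med = np.clip(med, lo, hi)
    return PredictionBand(med, lo, hi, horizon_start)


def retrodictive_check(
    series: ObservationSeries,
    posterior,
    model: ModelSpec,
    n: int = 100,
    seed: int = 0,
    sma_period: int = 0,
) -> PredictionBand:
    """Re-simulate the observed span from per-step posterior draws.

    For each of ``n`` re-simulations one posterior draw index supplies the
    trial-wise parameters theta_t; the observation model then generates a
    synthetic series, and the collection is summarized by the median and
    central 95% interval (optionally SMA-smoothed first).
    """
    T = len(series)
    theta = posterior.theta  # (T, n_draws, d)
    if theta.shape[0] < T:
        raise ValueError("posterior does not cover the observed span")
    if posterior.n_draws < n:
        raise ValueError("not enough posterior draws for the requested n")
    rng = np.random.default_rng(seed)
    idx = rng.choice(posterior.n_draws, size=n, replace=False)
    sims = np.empty((n, T))
    for i, j in enumerate(idx):
        traj = ParameterTrajectory(
            np.vstack([theta[0, j], theta[:T, j]]), posterior.theta_names)
        if series.kind == "poisson":
            sim = _observe_poisson(traj, rng)
        else:
            sim = _observe_ddm(model.low, traj, rng, conditions=series.condition)
        sims[i] = _series_values(sim)
    return _summarize(sims, 0, sma_period)


def multi_horizon_predict(
    theta_draws: np.ndarray,
    eta_draws: np.ndarray,
    horizon: int,
    model: ModelSpec,
    seed: int = 0,
    n: int | None = None,
    sma_period: int = 0,
    conditions: np.ndarray | None = None,
) -> PredictionBand:
    """Simulate future observations from joint posterior draws at time t0.

    Each draw j supplies an initial parameter row ``theta_draws[j]`` and its
    matching high-level vector ``eta_draws[j]``; a fresh transition
    trajectory of length ``horizon`` is rolled forward and observed.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if horizon == 0:
        return PredictionBand(np.empty(0), np.empty(0), np.empty(0), 0)
    theta_draws = np.atleast_2d(theta_draws)
    n = n or len(theta_draws)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(theta_draws), size=n, replace=n > len(theta_draws))
    sims = np.empty((n, horizon))
    eta_names = model.transition.eta_names
    for i, j in enumerate(idx):
        eta = HighLevelParams(eta_names, eta_draws[j] if len(eta_names) else np.empty(0))
        traj = simulate_trajectory(model, eta, theta_draws[j], horizon, rng)
        if model.low.kind == "poisson":
            sim = _observe_poisson(traj, rng)
        else:
            sim = _observe_ddm(model.low, traj, rng, conditions=conditions)
        sims[i] = _series_values(sim)
    return _summarize(sims, 0, sma_period)


def band_coverage(band: PredictionBand, observed: np.ndarray,
                  sma_period: int = 0) -> float:
    """Fraction of (optionally smoothed) observed points inside the band."""
    obs = sma(observed, sma_period) if sma_period > 1 else np.asarray(observed, float)
    if len(obs) != len(band):
        raise ValueError("band and series lengths differ")
    return float(np.mean((obs >= band.lower) & (obs <= band.upper)))


# ---------------------------------------------------------------------------
# maximum mean discrepancy
# ---------------------------------------------------------------------------


def mmd(sample_a: np.ndarray, sample_b: np.ndarray,
        bandwidth: float | None = None) -> float:
    """Unbiased squared-MMD estimate with a Gaussian kernel.

    The bandwidth defaults to the median heuristic (median pairwise distance
    over the pooled sample).  Negative estimates (possible for the unbiased
    U-statistic under the null) are clipped to 0 for reporting.
    """
    a = np.atleast_2d(np.asarray(sample_a, dtype=float))
    b = np.atleast_2d(np.asarray(sample_b, dtype=float))
    if a.ndim == 2 and a.shape[0] == 1 and np.asarray(sample_a).ndim == 1:
        a = a.T
    if b.ndim == 2 and b.shape[0] == 1 and np.asarray(sample_b).ndim == 1:
        b = b.T
    if a.shape[1] != b.shape[1]:
        raise ValueError("samples have different dimensions")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two points per sample")

    def sqdists(x, y):
        return ((x[:, None, :] - y[None, :, :]) ** 2).sum(-1)

    daa, dbb, dab = sqdists(a, a), sqdists(b, b), sqdists(a, b)
    if bandwidth is None:
        pooled = np.concatenate([
            daa[np.triu_indices(len(a), 1)],
            dbb[np.triu_indices(len(b), 1)],
            dab.ravel(),
        ])
        med = np.median(pooled)
        bandwidth = float(np.sqrt(med / 2.0)) if med > 0 else 1.0
    g = 1.0 / (2.0 * bandwidth**2)
    kaa = np.exp(-g * daa)
    kbb = np.exp(-g * dbb)
    kab = np.exp(-g * dab)
    m, n = len(a), len(b)
    term_a = (kaa.sum() - np.trace(kaa)) / (m * (m - 1))
    term_b = (kbb.sum() - np.trace(kbb)) / (n * (n - 1))
    return float(max(term_a + term_b - 2.0 * kab.mean(), 0.0))


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def sma(series: np.ndarray, period: int) -> np.ndarray:
    """Trailing simple moving average; the first period-1 entries average the
    available prefix so the output has the input's length."""
    x = np.asarray(series, dtype=float)
    if period < 1:
        raise ValueError("period must be >= 1")
    if period > len(x):
        warnings.warn("SMA period exceeds series length; using prefix means")
        period = len(x)
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty_like(x)
    head = min(period - 1, len(x))
    out[:head] = c[1:head + 1] / np.arange(1, head + 1)
    out[period - 1:] = (c[period:] - c[:-period]) / period
    return out
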