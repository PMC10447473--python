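"""Packaged benchmark studies at desk scale.

These functions bundle the training configurations and evaluation
procedures used to validate the amortized filter:

- the coal-mining-style Poisson benchmark: neural filter vs. the lattice
  filter on held-out synthetic count series;
- the static-DDM benchmark: fitting the random-walk DDM network to data
  from a static generator (posterior contraction, no pseudo-dynamics);
- the simulation-study recovery benchmark: truth vs. posterior mean on
  well-specified non-stationary (random-walk) DDM series;
- multi-horizon predictive coverage on held-out trial blocks.

Problem sizes are deliberately modest (a few thousand training simulations,
series of a few hundred trials) so a full benchmark run completes on a
single CPU in minutes; every function takes an explicit seed.
"""

from __future__ import annotations

import numpy as np

from .gridfilter import grid_filter_run
from .models import ModelSpec, ObservationSeries, ddm_model, poisson_random_walk_model, simulate_dataset
from .neural import AmortizedFilter, TrainingConfig
from .validation import band_coverage, multi_horizon_predict

__all__ = [
    "poisson_benchmark_config", "ddm_benchmark_config",
    "train_poisson_benchmark", "train_ddm_benchmark",
    "compare_neural_vs_grid", "pseudo_dynamics_report",
    "recovery_at_checkpoint", "multi_horizon_coverage",
    "series_prefix",
]


def poisson_benchmark_config(seed: int = 3) -> TrainingConfig:
    """Reduced-budget training settings for the Poisson + random-walk model."""
    return TrainingConfig(n_sim=5120, epochs=30, batch_size=128, T=110,
                          learning_rate=3e-3, head="gaussian", hidden=128,
                          n_pilot=1000, seed=seed)


def ddm_benchmark_config(seed: int = 11) -> TrainingConfig:
    """Reduced-budget training settings for the random-walk DDM."""
    return TrainingConfig(n_sim=3072, epochs=16, batch_size=256, T=300,
                          learning_rate=3.5e-3, head="gaussian", hidden=64,
                          n_pilot=1000, seed=seed)


def train_poisson_benchmark(seed: int = 3) -> AmortizedFilter:
    model = poisson_random_walk_model()
    af = AmortizedFilter(model, poisson_benchmark_config(seed))
    af.train()
    return af


def train_ddm_benchmark(seed: int = 11) -> AmortizedFilter:
    model = ddm_model("random_walk")
    af = AmortizedFilter(model, ddm_benchmark_config(seed))
    af.train()
    return af


def series_prefix(series: ObservationSeries, T: int) -> ObservationSeries:
    """First T entries of a series (filtering posteriors at t <= T only
    depend on this prefix)."""
    if series.kind == "poisson":
        return ObservationSeries(kind="poisson", counts=series.counts[:T])
    return ObservationSeries(
        kind="ddm", rt=series.rt[:T], choice=series.choice[:T],
        condition=series.condition[:T], timeout=series.timeout[:T],
        n_conditions=series.n_conditions,
    )


def compare_neural_vs_grid(
    af: AmortizedFilter,
    n_series: int = 20,
    T: int = 110,
    seed: int = 100_000,
    n_draws: int = 2000,
    lam_grid=(0.0, 15.0, 400),
    sigma_grid=(0.0, 1.0, 40),
) -> dict:
    """Neural vs. lattice posterior-mean rate trajectories on held-out series.

    Returns per-series MAE and Pearson correlation plus their means.
    """
    model = af.model
    maes, corrs = [], []
    for k in range(n_series):
        rec = simulate_dataset(model, T, seed + k)
        fp = af.filter(rec.series, n_draws=n_draws, seed=seed + k)
        neural = fp.theta_mean()[:, 0]
        grid = grid_filter_run(rec.series.counts, lam_grid, sigma_grid)
        maes.append(float(np.abs(neural - grid.mean).mean()))
        corrs.append(float(np.corrcoef(neural, grid.mean)[0, 1]))
    return {"mae": np.array(maes), "corr": np.array(corrs),
            "mae_mean": float(np.mean(maes)), "corr_mean": float(np.mean(corrs))}


def pseudo_dynamics_report(
    af: AmortizedFilter,
    n_series: int = 20,
    T: int = 100,
    seed: int = 300_000,
    n_draws: int = 500,
    burn_in: int = 25,
) -> dict:
    """Fit the dynamic network to static-generator data.

    Reports, per parameter: the SD over time of the across-fits mean
    posterior-mean trajectory after ``burn_in`` (systematic pseudo-dynamics;
    data-driven wobble of individual fits cancels in the average), the
    median marginal posterior SD, their ratio, and the median posterior SD
    at the first and last time steps (contraction).
    """
    static = ddm_model("static")
    M, S = [], []
    for k in range(n_series):
        rec = simulate_dataset(static, T, seed + k)
        fp = af.filter(rec.series, n_draws=n_draws, seed=seed + k)
        M.append(fp.theta_mean())
        S.append(fp.theta_sd())
    M, S = np.stack(M), np.stack(S)
    agg = M.mean(axis=0)
    wobble = agg[burn_in:].std(axis=0)
    sd_med = np.median(S[:, burn_in:, :], axis=(0, 1))
    return {
        "param_names": af.model.low.param_names,
        "wobble": wobble,
        "posterior_sd": sd_med,
        "ratio": wobble / sd_med,
        "sd_early": np.median(S[:, 4, :], axis=0),   # t = 5
        "sd_late": np.median(S[:, T - 1, :], axis=0),
        "per_series_wobble": M[:, burn_in:, :].std(axis=1),
    }


def recovery_at_checkpoint(
    af: AmortizedFilter,
    n_series: int = 50,
    T: int = 400,
    t_check: int = 99,
    seed: int = 200_000,
    n_draws: int = 500,
) -> dict:
    """Truth vs. posterior-mean correlation at one time point across series."""
    model = af.model
    truths, means = [], []
    for k in range(n_series):
        rec = simulate_dataset(model, T, seed + k)
        prefix = series_prefix(rec.series, t_check + 1)
        fp = af.filter(prefix, n_draws=n_draws, seed=seed + k)
        truths.append(rec.trajectory.values[t_check])
        means.append(fp.theta_mean()[t_check - 1])
    truths, means = np.array(truths), np.array(means)
    corr = {name: float(np.corrcoef(truths[:, j], means[:, j])[0, 1])
            for j, name in enumerate(model.low.param_names)}
    return {"truths": truths, "means": means, "corr": corr}


def multi_horizon_coverage(
    af: AmortizedFilter,
    n_series: int = 50,
    T: int = 400,
    horizon: int = 100,
    seed: int = 400_000,
    n_draws: int = 200,
    n_pred: int = 100,
    sma_period: int = 5,
) -> dict:
    """Coverage of the 95% multi-horizon band on held-out trial blocks.

    Each replicate fits the filter to the first T - horizon trials, then
    propagates joint (theta, eta) draws through the transition model for
    ``horizon`` steps and checks what fraction of the smoothed held-out
    series lies inside the 95% band.
    """
    model: ModelSpec = af.model
    t0 = T - horizon
    fracs = []
    for k in range(n_series):
        rec = simulate_dataset(model, T, seed + k)
        prefix = series_prefix(rec.series, t0)
        fp = af.filter(prefix, n_draws=n_draws, seed=seed + k)
        band = multi_horizon_predict(fp.theta[t0 - 1], fp.eta[t0 - 1], horizon,
                                     model, seed=seed + k, n=n_pred,
                                     sma_period=sma_period)
        held_out = rec.series.rt[t0:] if model.low.kind == "ddm" else rec.series.counts[t0:]
        fracs.append(band_coverage(band, held_out, sma_period=sma_period))
    fracs = np.array(fracs)
    return {"per_replicate": fracs, "mean_coverage": float(fracs.mean()),
            "frac_contained": float((fracs >= 0.9).mean())}
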