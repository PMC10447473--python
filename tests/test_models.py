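"""Generative family: transition kernels, trajectories, full simulation."""

import numpy as np
import pytest

from superstat.models import (
    HighLevelParams,
    ddm_model,
    gp_kernel,
    poisson_random_walk_model,
    sample_gp_trajectory,
    sample_prior,
    simulate_dataset,
    simulate_trajectory,
    transition_itv,
    transition_random_walk,
    transition_regime_switch,
    transition_var,
)
from superstat.priors import ConfigurationError


# ---------------------------------------------------------------------------
# prior sampling
# ---------------------------------------------------------------------------

def test_sample_prior_respects_supports_and_seed():
    model = poisson_random_walk_model()
    th0, eta = sample_prior(model.low, model.transition, 2000, seed=4)
    assert th0.shape == (2000, 1) and eta.shape == (2000, 1)
    assert np.all(th0 > 0)
    assert np.all((eta >= 0) & (eta <= 1))  # sigma ~ Beta(1, 25)
    th0b, etab = sample_prior(model.low, model.transition, 2000, seed=4)
    np.testing.assert_array_equal(th0, th0b)
    np.testing.assert_array_equal(eta, etab)


# ---------------------------------------------------------------------------
# transition kernels
# ---------------------------------------------------------------------------

def test_random_walk_direct_substitution():
    out = transition_random_walk(np.array([1.0]), np.array([0.0]), np.array([0.7]))
    assert out[0] == pytest.approx(1.0)
    out = transition_random_walk(np.array([1.0]), np.array([0.1]), np.array([1.0]))
    assert out[0] == pytest.approx(1.1)


def test_random_walk_increment_scale_and_normality(rng):
    # 1e5 increments at sigma=0.05: SD within 3 MC SE, excess kurtosis ~ 0
    n = 100_000
    xi = rng.standard_normal(n)
    incr = transition_random_walk(np.zeros(n), np.full(n, 0.05), xi)
    se_sd = 0.05 / np.sqrt(2 * n)
    assert abs(incr.std() - 0.05) < 3 * se_sd
    z = incr / 0.05
    assert abs((z**4).mean() - 3.0) < 3 * np.sqrt(24.0 / n)


def test_random_walk_rejects_negative_scale():
    with pytest.raises(ValueError):
        transition_random_walk(np.zeros(2), np.array([0.1, -0.1]), np.zeros(2))


def test_var_reduces_to_identity_and_substitution():
    th = np.array([[2.0, 2.0]])
    out = transition_var(th, np.zeros(2), [np.eye(2)], np.zeros(2))
    np.testing.assert_allclose(out, [2.0, 2.0])
    out = transition_var(th, np.zeros(2), [0.5 * np.eye(2)], np.zeros(2))
    np.testing.assert_allclose(out, [1.0, 1.0])


def test_var_stationary_mean_matches_closed_form(rng):
    # VAR(1), c=1, A=0.6 I: stationary mean c / (1 - 0.6) = 2.5
    c, a, sig = np.array([1.0]), 0.6, 0.2
    x = np.zeros(1)
    samples = []
    for t in range(20_000):
        x = transition_var(x[None], c, [a * np.eye(1)], sig * rng.standard_normal(1))
        if t > 500:
            samples.append(x[0])
    assert np.mean(samples) == pytest.approx(2.5, abs=0.05)


def test_var_shape_mismatch_is_an_error():
    with pytest.raises(ValueError):
        transition_var(np.zeros((1, 2)), np.zeros(2), [np.eye(3)], np.zeros(2))


def test_gp_kernel_matrices_are_symmetric_psd():
    for T in (8, 64, 512):
        for sig, ell in [(0.1, 0.05), (1.0, 0.3), (2.0, 1.0)]:
            K = gp_kernel(np.linspace(0, 1, T), sig, ell)
            np.testing.assert_allclose(K, K.T)
            K[np.diag_indices_from(K)] += 1e-6
            np.linalg.cholesky(K)  # raises if not PD


def test_gp_zero_amplitude_is_constant(rng):
    traj = sample_gp_trajectory(50, np.array([0.0]), np.array([0.2]),
                                np.array([1.5]), rng)
    np.testing.assert_allclose(traj, 1.5, atol=1e-4)


def test_gp_empirical_covariance_matches_kernel(rng):
    # Monte-Carlo check of the squared-exponential covariance over draws
    T, sig, ell = 20, 0.8, 0.25
    draws = np.stack([
        sample_gp_trajectory(T, np.array([sig]), np.array([ell]),
                             np.array([0.0]), rng)[:, 0]
        for _ in range(10_000)
    ])
    tgrid = np.linspace(0, 1, T + 1)
    K = gp_kernel(tgrid, sig, ell)
    for (i, j) in [(0, 0), (5, 5), (3, 10), (0, 20)]:
        emp = np.mean(draws[:, i] * draws[:, j])
        se = np.sqrt((K[i, i] * K[j, j] + K[i, j] ** 2) / len(draws))
        assert abs(emp - K[i, j]) < 3 * se, (i, j)


def test_gp_long_length_scale_gives_flat_paths(rng):
    traj = sample_gp_trajectory(100, np.array([1.0]), np.array([50.0]),
                                np.array([0.0]), rng)
    # per-path variation over t much smaller than the amplitude
    assert traj[:, 0].std() < 0.05


def test_gp_rejects_nonpositive_length_scale(rng):
    with pytest.raises(ValueError):
        sample_gp_trajectory(10, np.array([1.0]), np.array([0.0]),
                             np.array([0.0]), rng)


def test_regime_switch_identity_off_switch_times(rng):
    th = np.array([0.3, 0.7])
    out = transition_regime_switch(th, 57, (100, 200), [(0, 1), (0, 1)], rng)
    np.testing.assert_array_equal(out, th)
    out = transition_regime_switch(th, 100, (100, 200), [(0, 1), (0, 1)], rng)
    assert np.all((out >= 0) & (out <= 1))


def test_regime_switch_trajectory_has_four_segments():
    model = ddm_model("regime_switch", switch_times=(100, 200, 300))
    rec = simulate_dataset(model, 400, seed=9)
    vals = rec.trajectory.values
    change = np.any(np.diff(vals, axis=0) != 0, axis=1)
    assert list(np.flatnonzero(change) + 1) == [100, 200, 300]


def test_regime_switch_time_beyond_series_is_config_error():
    model = ddm_model("regime_switch", switch_times=(100, 200, 300))
    with pytest.raises(ConfigurationError):
        simulate_dataset(model, 250, seed=0)


def test_itv_zero_scale_is_constant_and_memoryless(rng):
    out = transition_itv(np.array([2.0]), np.array([0.0]), rng)
    assert out[0] == 2.0
    xs = np.array([transition_itv(np.array([0.0]), np.array([0.3]), rng)[0]
                   for _ in range(20_000)])
    assert abs(xs.std() - 0.3) < 3 * 0.3 / np.sqrt(2 * len(xs))
    r1 = np.corrcoef(xs[:-1], xs[1:])[0, 1]
    assert abs(r1) < 3 / np.sqrt(len(xs))


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def test_static_transition_keeps_theta_constant():
    rec = simulate_dataset(ddm_model("static"), 50, seed=1)
    assert np.all(rec.trajectory.values == rec.trajectory.values[0])


def test_simulation_record_is_bit_reproducible():
    model = ddm_model("random_walk")
    a = simulate_dataset(model, 60, seed=42)
    b = simulate_dataset(model, 60, seed=42)
    np.testing.assert_array_equal(a.trajectory.values, b.trajectory.values)
    np.testing.assert_array_equal(a.series.rt, b.series.rt)
    np.testing.assert_array_equal(a.series.choice, b.series.choice)
    np.testing.assert_array_equal(a.eta.values, b.eta.values)


@pytest.mark.parametrize("preset,T", [
    ("poisson", 110), ("rw", 120), ("gp", 80), ("itv", 60),
])
def test_trajectories_stay_inside_declared_support(preset, T):
    if preset == "poisson":
        model = poisson_random_walk_model()
    else:
        model = ddm_model({"rw": "random_walk", "gp": "gp", "itv": "itv"}[preset])
    for seed in range(100):
        rec = simulate_dataset(model, T, seed=seed)
        assert model.low.in_support(rec.trajectory.values), seed
        assert len(rec.series) == T


def test_poisson_coal_scale_record():
    rec = simulate_dataset(poisson_random_walk_model(), 110, seed=8)
    assert len(rec.series.counts) == 110
    assert np.all(rec.series.counts >= 0)
    assert rec.eta.names == ("sigma_lam",)


def test_multi_condition_ddm_uses_matching_drift():
    model = ddm_model("random_walk", n_conditions=4)
    rec = simulate_dataset(model, 200, seed=5)
    assert set(np.unique(rec.series.condition)) <= {0, 1, 2, 3}
    assert rec.trajectory.values.shape[1] == 6  # v1..v4, a, tau


def test_gp_trajectory_starts_at_prior_draw():
    model = ddm_model("gp")
    rec = simulate_dataset(model, 50, seed=2)
    # row 0 must be the theta_0 prior draw: re-simulating with same seed but
    # different T keeps row 0 identical
    rec2 = simulate_dataset(model, 80, seed=2)
    np.testing.assert_allclose(rec.trajectory.values[0], rec2.trajectory.values[0])
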