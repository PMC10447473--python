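"""Model criticism: SBC controls, recovery metrics, bands, MMD, SMA."""

import numpy as np
import pytest
from scipy import stats

from superstat.models import ddm_model, poisson_random_walk_model, simulate_dataset
from superstat.neural import FilterPosterior
from superstat.validation import (
    PredictionBand,
    band_coverage,
    ecdf_band_violation,
    mmd,
    multi_horizon_predict,
    recovery,
    retrodictive_check,
    sbc,
    sbc_ranks_uniformity,
    sma,
)


# ---------------------------------------------------------------------------
# static conjugate model used as an exactly calibrated posterior sampler
# ---------------------------------------------------------------------------

def _static_poisson_model():
    model = poisson_random_walk_model()
    # sigma identically ~0 makes the transition effectively static: the true
    # posterior is conjugate Gamma(1 + sum x, 0.5 + t)
    from superstat.priors import PriorSpec

    model.transition.eta_priors["sigma_lam"] = PriorSpec(
        "uniform", {"lower": 0.0, "upper": 1e-9}, name="sigma_lam")
    return model


def _conjugate_sampler(shift=0.0):
    def sampler(series, n_draws, seed):
        rng = np.random.default_rng(seed)
        out = {}
        csum = np.cumsum(series.counts)
        for t in range(len(series)):
            draws = rng.gamma(1 + csum[t], 1 / (0.5 + t + 1), size=n_draws) + shift
            out[t] = draws[:, None]
        return out
    return sampler


def test_rank_definition_extremes():
    model = _static_poisson_model()

    def low_sampler(series, n_draws, seed):
        return {t: np.full((n_draws, 1), 1e9) for t in range(len(series))}

    res = sbc(model, low_sampler, n_sim=100, n_draws=20, checkpoints=[9], T=10,
              seed=0)
    assert np.all(res.ranks[("lam", 9)] == 0)  # truth below every draw


def test_conjugate_sampler_is_calibrated_and_shifted_is_not():
    model = _static_poisson_model()
    res = sbc(model, _conjugate_sampler(), n_sim=200, n_draws=250,
              checkpoints=[29], T=30, seed=1)
    assert res.ks_pvalue[("lam", 29)] > 0.01
    res_bad = sbc(model, _conjugate_sampler(shift=0.5), n_sim=200, n_draws=250,
                  checkpoints=[29], T=30, seed=1)
    assert res_bad.ks_pvalue[("lam", 29)] < 0.01
    assert res_bad.ecdf_violation[("lam", 29)] > res.ecdf_violation[("lam", 29)]


def test_sbc_warns_when_underpowered():
    model = _static_poisson_model()
    with pytest.warns(UserWarning, match="underpowered"):
        sbc(model, _conjugate_sampler(), n_sim=20, n_draws=50,
            checkpoints=[4], T=5, seed=0)


def test_ecdf_band_accepts_uniform_ranks():
    rng = np.random.default_rng(0)
    ranks = rng.integers(0, 251, size=300)
    assert ecdf_band_violation(ranks, 250) == 0.0


def test_ks_uniformity_helper():
    rng = np.random.default_rng(1)
    s, p = sbc_ranks_uniformity(rng.integers(0, 101, 500), 100)
    assert p > 0.01 and 0 <= s <= 1


# ---------------------------------------------------------------------------
# recovery
# ---------------------------------------------------------------------------

def _fake_posterior(means, sd=0.1):
    T, d = means.shape
    theta = means[:, None, :] + np.zeros((T, 50, d))
    theta += sd * np.random.default_rng(0).standard_normal(theta.shape)
    return FilterPosterior(theta, np.zeros((T, 50, 0)), ("v", "a", "tau"), ())


def test_recovery_perfect_and_offset_closed_forms():
    model = ddm_model("static")
    recs = [simulate_dataset(model, 20, seed=s) for s in range(6)]
    perfect = [_fake_posterior(r.trajectory.values[1:], sd=0.0) for r in recs]
    rep = recovery(recs, perfect, scatter_at=[10])
    np.testing.assert_allclose(rep.mae, 0.0, atol=1e-12)
    for p in ("v", "a", "tau"):
        assert rep.correlation[(p, 10)] > 0.999
    offset = [_fake_posterior(r.trajectory.values[1:] + 0.7, sd=0.0) for r in recs]
    rep = recovery(recs, offset)
    np.testing.assert_allclose(rep.mae, 0.7, atol=1e-9)


def test_recovery_length_mismatch_raises():
    model = ddm_model("static")
    recs = [simulate_dataset(model, 20, seed=0)]
    with pytest.raises(ValueError):
        recovery(recs, [])


# ---------------------------------------------------------------------------
# bands
# ---------------------------------------------------------------------------

def test_band_quantile_ordering_enforced():
    with pytest.raises(ValueError):
        PredictionBand(np.array([1.0]), np.array([2.0]), np.array([3.0]))


def test_retrodictive_band_covers_well_specified_poisson_data():
    from superstat.models import ObservationSeries

    model = poisson_random_walk_model()
    # a clearly moving latent rate with Poisson counts
    truth = np.linspace(6.0, 1.5, 80)[:, None]
    counts = np.random.default_rng(21).poisson(truth[:, 0])
    series = ObservationSeries(kind="poisson", counts=counts)
    rec = type("R", (), {"series": series})()
    theta = truth[:, None, :] * np.exp(
        0.05 * np.random.default_rng(0).standard_normal((80, 120, 1)))
    fp = FilterPosterior(theta, np.zeros((80, 120, 0)), ("lam",), ())
    band = retrodictive_check(rec.series, fp, model, n=100, seed=0, sma_period=5)
    cov = band_coverage(band, rec.series.counts, sma_period=5)
    assert cov >= 0.85
    # the band median tracks the latent rate trajectory
    assert np.corrcoef(band.median, sma(truth[:, 0], 5))[0, 1] > 0.5


def test_retrodiction_needs_enough_draws():
    model = poisson_random_walk_model()
    rec = simulate_dataset(model, 10, seed=0)
    fp = FilterPosterior(np.ones((10, 5, 1)), np.zeros((10, 5, 0)), ("lam",), ())
    with pytest.raises(ValueError):
        retrodictive_check(rec.series, fp, model, n=50)


def test_multi_horizon_zero_horizon_and_zero_noise():
    model = poisson_random_walk_model()
    band = multi_horizon_predict(np.array([[2.0]]), np.array([[0.001]]), 0, model)
    assert len(band) == 0
    # zero transition noise: only observation noise widens the band
    theta = np.full((100, 1), 4.0)
    eta = np.full((100, 1), 1e-12)
    band = multi_horizon_predict(theta, eta, 50, model, seed=1, n=100)
    assert np.all(band.lower >= 0) and np.all(band.upper <= 20)
    assert abs(band.median.mean() - 4.0) < 0.5


def test_multi_horizon_rejects_negative_horizon():
    with pytest.raises(ValueError):
        multi_horizon_predict(np.ones((2, 1)), np.ones((2, 1)), -1,
                              poisson_random_walk_model())


def test_band_coverage_length_check():
    band = PredictionBand(np.zeros(5), -np.ones(5), np.ones(5))
    assert band_coverage(band, np.zeros(5)) == 1.0
    with pytest.raises(ValueError):
        band_coverage(band, np.zeros(6))


# ---------------------------------------------------------------------------
# MMD
# ---------------------------------------------------------------------------

def _mmd_bruteforce(a, b, bw):
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    g = 1.0 / (2 * bw * bw)
    m, n = len(a), len(b)
    saa = sum(np.exp(-g * ((a[i] - a[j]) ** 2).sum())
              for i in range(m) for j in range(m) if i != j) / (m * (m - 1))
    sbb = sum(np.exp(-g * ((b[i] - b[j]) ** 2).sum())
              for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
    sab = sum(np.exp(-g * ((a[i] - b[j]) ** 2).sum())
              for i in range(m) for j in range(n)) / (m * n)
    return saa + sbb - 2 * sab


def test_mmd_matches_bruteforce_double_loop():
    rng = np.random.default_rng(2)
    a = rng.standard_normal((30, 2))
    b = rng.standard_normal((25, 2)) + 0.3
    got = mmd(a, b, bandwidth=1.0)
    expect = _mmd_bruteforce(a, b, 1.0)
    assert got == pytest.approx(max(expect, 0.0), abs=1e-10)


def test_mmd_identical_samples_is_zero():
    rng = np.random.default_rng(3)
    a = rng.standard_normal((50, 1))
    assert mmd(a, a.copy()) == pytest.approx(0.0, abs=1e-8)


def test_mmd_null_small_and_alternative_exceeds_permutation_null():
    rng = np.random.default_rng(4)
    a = rng.standard_normal((1000, 1))
    b = rng.standard_normal((1000, 1))
    assert mmd(a, b) < 5e-3
    x = rng.standard_normal((200, 1))
    y = rng.standard_normal((200, 1)) + 3.0
    observed = mmd(x, y)
    pooled = np.concatenate([x, y])
    null = []
    for _ in range(99):
        rng.shuffle(pooled)
        null.append(mmd(pooled[:200], pooled[200:]))
    assert observed > np.quantile(null, 0.99)


def test_mmd_dimension_mismatch():
    with pytest.raises(ValueError):
        mmd(np.zeros((5, 2)), np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# SMA
# ---------------------------------------------------------------------------

def test_sma_closed_forms():
    x = np.arange(1.0, 11.0)
    out = sma(x, 5)
    assert out[-1] == pytest.approx(8.0)  # mean(6..10)
    np.testing.assert_allclose(sma(np.full(7, 3.0), 4), 3.0)
    np.testing.assert_allclose(sma(x, 1), x)
    # prefix handling keeps output length equal to input length
    assert out[0] == 1.0 and out[1] == 1.5


def test_sma_period_longer_than_series_warns():
    with pytest.warns(UserWarning):
        out = sma(np.arange(1.0, 4.0), 10)
    np.testing.assert_allclose(out, [1.0, 1.5, 2.0])


def test_sma_rejects_bad_period():
    with pytest.raises(ValueError):
        sma(np.arange(3.0), 0)
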