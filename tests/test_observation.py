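"""Observation models: Poisson PMF, DDM simulator vs. analytic oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from superstat.models import ParameterTrajectory, ddm_model, poisson_random_walk_model
from superstat.observation import (
    DDMParams,
    ddm_choice_probability,
    ddm_first_passage,
    ddm_mean_decision_time,
    observe,
    poisson_logpmf,
    simulate_ddm_trials,
    wfpt_density,
)


# ---------------------------------------------------------------------------
# Poisson emission
# ---------------------------------------------------------------------------

def test_poisson_logpmf_closed_forms():
    assert poisson_logpmf(0, 1.0) == pytest.approx(-1.0)
    assert poisson_logpmf(2, 2.0) == pytest.approx(np.log(2.0) - 2.0)


def test_poisson_pmf_normalizes():
    x = np.arange(201)
    total = np.exp(poisson_logpmf(x, 3.0)).sum()
    assert total == pytest.approx(1.0, abs=1e-12)


def test_poisson_rejects_bad_inputs():
    with pytest.raises(ValueError):
        poisson_logpmf(2, 0.0)
    with pytest.raises(ValueError):
        poisson_logpmf(-1, 1.0)


# ---------------------------------------------------------------------------
# DDM first-passage simulator
# ---------------------------------------------------------------------------

def test_zero_drift_is_symmetric():
    n = 10_000
    _, ch, _ = simulate_ddm_trials(np.zeros(n), np.full(n, 2.0), np.full(n, 0.3),
                                   seed=8)
    assert abs(ch.mean() - 0.5) < 3 * 0.5 / np.sqrt(n)


def test_rt_never_below_non_decision_time():
    n = 5000
    rt, _, to = simulate_ddm_trials(np.full(n, 0.5), np.full(n, 1.5),
                                    np.full(n, 0.4), seed=9)
    assert np.all(rt[~to] >= 0.4)


def test_single_trial_wrapper_and_timeout_flag():
    tr = ddm_first_passage(DDMParams(v=1.0, a=1.5, tau=0.25), seed=1)
    assert tr.rt >= 0.25 and tr.choice in (0, 1) and not tr.timeout
    # a huge threshold with tiny budget forces a timeout, which is flagged
    tr = ddm_first_passage(DDMParams(v=0.0, a=50.0, tau=0.2), t_max=0.5, seed=1)
    assert tr.timeout and tr.rt == 0.5


def test_invalid_params_raise():
    with pytest.raises(ValueError):
        DDMParams(v=1.0, a=-1.0, tau=0.3)
    with pytest.raises(ValueError):
        DDMParams(v=1.0, a=1.0, tau=0.0)
    with pytest.raises(ValueError):
        simulate_ddm_trials(np.zeros(1), np.ones(1), np.ones(1) * 0.3, dt=-1)


def test_euler_step_size_convergence():
    # halving dt twice changes choice rate and mean rt by less than MC error
    n = 6000
    p = dict(v=np.full(n, 1.0), a=np.full(n, 2.0), tau=np.full(n, 0.3))
    rt1, ch1, _ = simulate_ddm_trials(**p, dt=1e-3, seed=3)
    rt2, ch2, _ = simulate_ddm_trials(**p, dt=2.5e-4, seed=4)
    assert abs(ch1.mean() - ch2.mean()) < 3 * np.sqrt(2 * 0.11 * 0.89 / n)
    assert abs(rt1.mean() - rt2.mean()) < 3 * np.sqrt(2) * rt1.std() / np.sqrt(n)


def test_timeout_rate_under_default_priors():
    from superstat.models import simulate_dataset

    model = ddm_model("static")
    n_to = n_tot = 0
    for seed in range(100):
        rec = simulate_dataset(model, 100, seed=seed)
        n_to += rec.series.timeout.sum()
        n_tot += len(rec.series)
    assert n_to / n_tot < 1e-3


# ---------------------------------------------------------------------------
# Wiener first-passage density (analytic oracle)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("v,a,tau", [(1.0, 2.0, 0.3), (-0.5, 1.0, 0.2),
                                     (2.5, 0.8, 0.15), (0.0, 1.5, 0.3)])
def test_wfpt_density_integrates_to_choice_probabilities(v, a, tau):
    p = DDMParams(v=v, a=a, tau=tau)
    upper = quad(lambda r: wfpt_density(r, 1, p), tau, tau + 30, limit=300)[0]
    lower = quad(lambda r: wfpt_density(r, 0, p), tau, tau + 30, limit=300)[0]
    assert upper + lower == pytest.approx(1.0, abs=1e-4)
    assert upper == pytest.approx(ddm_choice_probability(v, a), abs=1e-4)


def test_wfpt_density_zero_before_non_decision_time():
    p = DDMParams(v=1.0, a=2.0, tau=0.3)
    assert wfpt_density(0.29, 1, p) == 0.0
    assert wfpt_density(0.3, 0, p) == 0.0


def test_simulator_agrees_with_wfpt_density():
    # binned RT probabilities of 1e5 simulated upper-boundary trials vs the
    # integrated analytic density
    n = 100_000
    p = DDMParams(v=1.0, a=2.0, tau=0.3)
    rt, ch, to = simulate_ddm_trials(np.full(n, p.v), np.full(n, p.a),
                                     np.full(n, p.tau), seed=11)
    assert to.sum() == 0
    edges = np.array([0.3, 0.5, 0.7, 0.9, 1.1, 1.4, 1.8, 2.5, 4.0, 10.0])
    sim_p = np.histogram(rt[ch == 1], bins=edges)[0] / n
    for i in range(len(edges) - 1):
        exact = quad(lambda r: wfpt_density(r, 1, p), edges[i], edges[i + 1],
                     limit=200)[0]
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(sim_p[i] - exact) < 4 * se + 1e-4, i


# ---------------------------------------------------------------------------
# series-level emission
# ---------------------------------------------------------------------------

def test_observe_poisson_matches_rate(rng):
    model = poisson_random_walk_model()
    traj = ParameterTrajectory(np.full((10_001, 1), 4.0), ("lam",))
    series = observe(traj, model.low, seed=2)
    assert abs(series.counts.mean() - 4.0) < 3 * 2.0 / np.sqrt(10_000)


def test_constant_trajectory_gives_iid_trials():
    model = ddm_model("static")
    traj = ParameterTrajectory(
        np.tile([1.0, 1.6, 0.3], (401, 1)), ("v", "a", "tau"))
    s1 = observe(traj, model.low, seed=5)
    # split-half comparison: same distribution in both halves
    a, b = s1.rt[:200], s1.rt[200:]
    assert abs(a.mean() - b.mean()) < 4 * np.sqrt(a.var() / 200 + b.var() / 200)


def test_condition_specific_drifts_order_accuracy():
    # v = (+2, +1, -1, -2): P(choice=1) must decrease across conditions
    model = ddm_model("static", n_conditions=4)
    T = 8000
    vals = np.tile([2.0, 1.0, -1.0, -2.0, 1.8, 0.3], (T + 1, 1))
    traj = ParameterTrajectory(vals, model.low.param_names)
    conditions = np.arange(T) % 4
    series = observe(traj, model.low, seed=3, conditions=conditions)
    acc = [series.choice[series.condition == c].mean() for c in range(4)]
    assert acc[0] > acc[1] > 0.5 > acc[2] > acc[3]
    # and the closed form predicts each rate
    for c, v in enumerate([2.0, 1.0, -1.0, -2.0]):
        expect = ddm_choice_probability(v, 1.8)
        assert abs(acc[c] - expect) < 4 * np.sqrt(expect * (1 - expect) / (T / 4))


def test_observe_rejects_bad_condition_codes():
    model = ddm_model("static", n_conditions=2)
    traj = ParameterTrajectory(np.tile([1.0, 0.5, 1.6, 0.3], (11, 1)),
                               model.low.param_names)
    with pytest.raises(ValueError):
        observe(traj, model.low, seed=0, conditions=np.full(10, 5))


def test_mean_decision_time_closed_form_limits():
    assert ddm_mean_decision_time(0.0, 2.0) == pytest.approx(1.0)  # a^2/4
    assert ddm_mean_decision_time(1.0, 2.0) == pytest.approx(np.tanh(1.0))
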