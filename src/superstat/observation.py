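"""Low-level observation models: Poisson emission and the DDM simulator.

The diffusion decision model (DDM) treats a two-choice decision as a drifting
random walk of accumulated evidence between two absorbing boundaries (0 and
``a``), starting at ``z = a/2``, with unit diffusion coefficient.  The
simulator integrates the SDE ``dx = v dt + sqrt(dt) N(0,1)`` with an
Euler–Maruyama scheme and adds the non-decision time ``tau`` to the first
crossing time.

:func:`wfpt_density` provides the closed-form Wiener first-passage-time
density (small-time / large-time series expansions, truncated adaptively) as
an analytic cross-check for the stochastic simulator; for the symmetric start
point, choice probabilities and mean decision times also have elementary
closed forms (:func:`ddm_choice_probability`, :func:`ddm_mean_decision_time`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import special

__all__ = [
    "DDMParams",
    "Trial",
    "poisson_logpmf",
    "simulate_ddm_trials",
    "ddm_first_passage",
    "wfpt_density",
    "ddm_choice_probability",
    "ddm_mean_decision_time",
    "observe",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class DDMParams:
    """Static DDM parameters: drift ``v``, threshold ``a``, non-decision ``tau``.

    Start point ``z`` defaults to ``a/2`` (unbiased); diffusion coefficient is
    fixed at 1.
    """

    v: float
    a: float
    tau: float
    z: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("threshold a must be positive")
        if self.tau <= 0:
            raise ValueError("non-decision time tau must be positive")
        if self.z is None:
            self.z = self.a / 2.0
        if not 0.0 < self.z < self.a:
            raise ValueError("start point must lie strictly between the boundaries")

    @property
    def w(self) -> float:
        """Relative start point z/a."""
        return self.z / self.a


@dataclass
class Trial:
    """A single simulated decision: response time, choice, condition, timeout."""

    rt: float
    choice: int
    condition: int = 0
    timeout: bool = False


# ---------------------------------------------------------------------------
# Poisson emission
# ---------------------------------------------------------------------------


def poisson_logpmf(x, lam) -> np.ndarray:
    """Exact Poisson log-PMF ``x log(lam) - lam - log(x!)``."""
    x = np.asarray(x)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("Poisson rate must be positive")
    if np.any(x < 0) or not np.issubdtype(x.dtype, np.integer) and np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    xf = x.astype(float)
    return xf * np.log(lam) - lam - special.gammaln(xf + 1.0)


# ---------------------------------------------------------------------------
# DDM first-passage simulation (Euler–Maruyama)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _simulate_core(v, a, z, tau, dt, t_max, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n = v.shape[0]
    rt = np.empty(n)
    choice = np.empty(n, dtype=np.int64)
    timeout = np.zeros(n, dtype=np.bool_)
    sqdt = math.sqrt(dt)
    for i in range(n):
        x = z[i]
        max_steps = int((t_max - tau[i]) / dt)
        steps = 0
        crossed = False
        while steps < max_steps:
            x_new = x + v[i] * dt + sqdt * np.random.normal(0.0, 1.0)
            steps += 1
            if x_new >= a[i]:
                choice[i] = 1
                crossed = True
            elif x_new <= 0.0:
                choice[i] = 0
                crossed = True
            else:
                # Brownian-bridge test for an unobserved crossing inside the
                # step; removes the O(sqrt(dt)) first-passage-time bias of the
                # naive end-point boundary check.
                p_up = math.exp(-2.0 * (a[i] - x) * (a[i] - x_new) / dt)
                p_lo = math.exp(-2.0 * x * x_new / dt)
                un = np.random.random()
                if un < p_up:
                    choice[i] = 1
                    crossed = True
                elif un < p_up + p_lo:
                    choice[i] = 0
                    crossed = True
            if crossed:
                break
            x = x_new
        if crossed:
            rt[i] = steps * dt + tau[i]
        else:
            timeout[i] = True
            choice[i] = 1 if x >= a[i] / 2.0 else 0
            rt[i] = t_max
    return rt, choice, timeout


def simulate_ddm_trials(
    v: np.ndarray,
    a: np.ndarray,
    tau: np.ndarray,
    dt: float = 1e-3,
    t_max: float = 10.0,
    seed: int = 0,
    z: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one decision per row of per-trial parameters.

    Returns ``(rt, choice, timeout)``.  Trials that fail to cross a boundary
    within ``t_max`` are flagged (not resampled) and keep ``rt = t_max``.
    """
    v = np.ascontiguousarray(v, dtype=np.float64)
    a = np.ascontiguousarray(a, dtype=np.float64)
    tau = np.ascontiguousarray(tau, dtype=np.float64)
    if not (v.shape == a.shape == tau.shape):
        raise ValueError("v, a, tau must have equal length")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.any(a <= 0) or np.any(tau <= 0):
        raise ValueError("a and tau must be positive")
    if np.any(t_max <= tau):
        raise ValueError("t_max must exceed every non-decision time")
    if z is None:
        z = a / 2.0
    z = np.ascontiguousarray(z, dtype=np.float64)
    return _simulate_core(v, a, z, tau, float(dt), float(t_max), int(seed))


def ddm_first_passage(
    params: DDMParams,
    dt: float = 1e-3,
    t_max: float = 10.0,
    seed: int = 0,
    condition: int = 0,
) -> Trial:
    """Simulate a single trial from :class:`DDMParams`."""
    rt, choice, to = simulate_ddm_trials(
        np.array([params.v]), np.array([params.a]), np.array([params.tau]),
        dt=dt, t_max=t_max, seed=seed, z=np.array([params.z]),
    )
    return Trial(float(rt[0]), int(choice[0]), condition, bool(to[0]))


# ---------------------------------------------------------------------------
# closed forms (symmetric and general start point, unit diffusion)
# ---------------------------------------------------------------------------


def ddm_choice_probability(v: float, a: float, w: float = 0.5) -> float:
    """P(upper boundary) for the two-boundary Wiener process."""
    if v == 0.0:
        return w
    # P(upper) = (1 - exp(-2 v a w)) / (1 - exp(-2 v a))
    num = -math.expm1(-2.0 * v * a * w)
    den = -math.expm1(-2.0 * v * a)
    return num / den


def ddm_mean_decision_time(v: float, a: float) -> float:
    """Mean first-passage time for a symmetric start (z = a/2)."""
    if v == 0.0:
        return a * a / 4.0
    return (a / (2.0 * v)) * math.tanh(v * a / 2.0)


# ---------------------------------------------------------------------------
# Wiener first-passage-time density (series expansions)
# ---------------------------------------------------------------------------


def _ftilde(u: float, w: float, err: float) -> float:
    """Normalized (v=0, a=1) lower-boundary FPT density at scaled time u."""
    if u <= 1e-12:
        return 0.0
    # choose between small-time and large-time expansions by the number of
    # terms each needs for truncation error below `err`
    if 2.0 * math.sqrt(2.0 * math.pi * u) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * err * math.sqrt(2.0 * math.pi * u)))
        ks = max(ks, math.sqrt(u) + 1.0)
    else:
        ks = 2.0
    if math.pi * u * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * err) / (math.pi**2 * u))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(u)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -int(math.floor((K - 1) / 2))
        hi = int(math.ceil((K - 1) / 2))
        s = 0.0
        for k in range(lo, hi + 1):
            s += (w + 2.0 * k) * math.exp(-((w + 2.0 * k) ** 2) / (2.0 * u))
        return s / math.sqrt(2.0 * math.pi * u**3)
    K = int(math.ceil(kl))  # large-time expansion
    s = 0.0
    for k in range(1, K + 1):
        s += k * math.exp(-(k**2) * math.pi**2 * u / 2.0) * math.sin(k * math.pi * w)
    return math.pi * s


def wfpt_density(
    rt: float, choice: int, params: DDMParams, err: float = 1e-7
) -> float:
    """First-passage density of (rt, choice) under the Wiener diffusion model.

    Returns 0 for ``rt <= tau``.  Integrating over rt for one choice yields
    that boundary's choice probability; integrating over both choices yields 1.
    """
    t = rt - params.tau
    if t <= 0.0:
        return 0.0
    v, a, w = params.v, params.a, params.w
    if choice == 1:  # upper boundary: reflect
        v, w = -v, 1.0 - w
    u = t / (a * a)
    f = _ftilde(u, w, err)
    return f * math.exp(-v * a * w - v * v * t / 2.0) / (a * a)


# ---------------------------------------------------------------------------
# series-level emission
# ---------------------------------------------------------------------------


def observe(trajectory, low, seed: int, conditions=None, dt: float = 1e-3,
            t_max: float = 10.0):
    """Emit an :class:`~superstat.models.ObservationSeries` from a trajectory.

    Trial ``t`` uses parameter row ``theta_t`` (row ``t`` of the trajectory,
    rows 1..T) and, for the multi-condition DDM, the drift matching the trial's
    condition code.
    """
    from .models import _observe_ddm, _observe_poisson

    rng = np.random.default_rng(seed)
    if low.kind == "poisson":
        return _observe_poisson(trajectory, rng)
    return _observe_ddm(low, trajectory, rng, conditions, dt=dt, t_max=t_max)
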