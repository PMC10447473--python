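"""Superstatistical model family: priors, transition models, simulators.

A model couples a *low-level* observation model (Poisson counts or the
diffusion decision model, DDM) whose parameters ``theta_t`` drift over time
according to a *high-level* transition model (static, Gaussian random walk,
vector autoregression, Gaussian process, regime switching, or memoryless
inter-trial variability) with static hyperparameters ``eta``.

Transitions act on an unconstrained scale: strictly positive DDM parameters
(threshold ``a``, non-decision time ``tau``) are log-transformed before the
transition noise is applied, so Gaussian increments never leave the support.
The Poisson rate ``lambda`` is the one exception — its random walk acts on
the natural scale with a small positive floor, mirroring the lattice filter
(:mod:`superstat.gridfilter`) that propagates a Gaussian kernel in rate
units, so that the neural and grid methods target the same generative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import ConfigurationError, PriorSpec

__all__ = [
    "LowLevelSpec",
    "TransitionSpec",
    "ModelSpec",
    "HighLevelParams",
    "ParameterTrajectory",
    "ObservationSeries",
    "SimulationRecord",
    "sample_prior",
    "transition_random_walk",
    "transition_var",
    "sample_gp_trajectory",
    "transition_regime_switch",
    "transition_itv",
    "simulate_trajectory",
    "simulate_dataset",
    "poisson_random_walk_model",
    "ddm_model",
]

_TRANSITION_KINDS = ("static", "random_walk", "var", "gp", "regime_switch", "itv")

# floor for positive parameters handled on the natural scale (Poisson rate)
_RATE_FLOOR = 1e-3


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class LowLevelSpec:
    """Declaration of the observation model.

    ``transforms`` maps each parameter to ``"log"`` or ``"identity"``; the
    transition model operates on the transformed scale.  ``bounds`` are hard
    support limits on the natural scale, enforced on every trajectory.
    """

    kind: str  # "poisson" | "ddm"
    param_names: tuple[str, ...]
    theta0_priors: dict[str, PriorSpec]
    transforms: dict[str, str]
    bounds: dict[str, tuple[float, float]]
    n_conditions: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "ddm"):
            raise ConfigurationError(f"unknown low-level model kind {self.kind!r}")
        for name in self.param_names:
            if name not in self.theta0_priors:
                raise ConfigurationError(f"missing theta_0 prior for {name!r}")
            if self.transforms.get(name) not in ("log", "identity"):
                raise ConfigurationError(f"missing/invalid transform for {name!r}")
        if self.kind == "ddm":
            n_drifts = sum(1 for n in self.param_names if n.startswith("v"))
            if n_drifts != self.n_conditions:
                raise ConfigurationError(
                    f"{n_drifts} drift parameters declared but "
                    f"n_conditions={self.n_conditions}"
                )

    @property
    def dim(self) -> int:
        return len(self.param_names)

    # transformed <-> natural scale -------------------------------------
    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        out = theta.copy()
        for j, name in enumerate(self.param_names):
            if self.transforms[name] == "log":
                out[..., j] = np.log(theta[..., j])
        return out

    def to_natural(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        out = u.copy()
        for j, name in enumerate(self.param_names):
            if self.transforms[name] == "log":
                out[..., j] = np.exp(u[..., j])
            lo, hi = self.bounds[name]
            out[..., j] = np.clip(out[..., j], lo, hi)
        return out

    def in_support(self, theta: np.ndarray) -> bool:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        for j, name in enumerate(self.param_names):
            lo, hi = self.bounds[name]
            if np.any(theta[:, j] < lo) or np.any(theta[:, j] > hi):
                return False
        return True


@dataclass
class TransitionSpec:
    """Declaration of the high-level transition model."""

    kind: str
    eta_priors: dict[str, PriorSpec] = field(default_factory=dict)
    var_order: int = 1
    switch_times: tuple[int, ...] = ()
    jump_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _TRANSITION_KINDS:
            raise ConfigurationError(f"unknown transition kind {self.kind!r}")
        if self.kind == "var" and self.var_order < 1:
            raise ConfigurationError("VAR order p must be >= 1")
        if self.kind == "regime_switch":
            st = self.switch_times
            if any(b <= a for a, b in zip(st, st[1:])):
                raise ConfigurationError("switch times must be strictly increasing")

    @property
    def eta_names(self) -> tuple[str, ...]:
        return tuple(self.eta_priors.keys())

    @property
    def eta_dim(self) -> int:
        return len(self.eta_priors)


@dataclass
class ModelSpec:
    """A complete generative model: observation model + transition model."""

    low: LowLevelSpec
    transition: TransitionSpec
    name: str = "model"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class HighLevelParams:
    """Named static transition-model parameter vector eta."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("eta vector length does not match names")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


@dataclass
class ParameterTrajectory:
    """theta_{0:T}: (T+1, d) matrix of low-level parameters, natural scale."""

    values: np.ndarray  # (T+1, d)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names):
            raise ValueError("trajectory width does not match parameter names")

    @property
    def T(self) -> int:
        return self.values.shape[0] - 1


@dataclass
class ObservationSeries:
    """Observed series x_{1:T}: counts, or (rt, choice, condition) triples."""

    kind: str
    counts: np.ndarray | None = None
    rt: np.ndarray | None = None
    choice: np.ndarray | None = None
    condition: np.ndarray | None = None
    timeout: np.ndarray | None = None
    n_conditions: int = 1

    def __post_init__(self) -> None:
        if self.kind == "poisson":
            if self.counts is None:
                raise ValueError("poisson series needs counts")
            self.counts = np.asarray(self.counts)
            if np.any(self.counts < 0):
                raise ValueError("counts must be non-negative")
        elif self.kind == "ddm":
            if self.rt is None or self.choice is None:
                raise ValueError("ddm series needs rt and choice")
            self.rt = np.asarray(self.rt, dtype=float)
            self.choice = np.asarray(self.choice, dtype=int)
            if self.condition is None:
                self.condition = np.zeros(len(self.rt), dtype=int)
            self.condition = np.asarray(self.condition, dtype=int)
            if self.timeout is None:
                self.timeout = np.zeros(len(self.rt), dtype=bool)
            self.timeout = np.asarray(self.timeout, dtype=bool)
            if np.any(self.rt <= 0):
                raise ValueError("response times must be positive")
            if np.any((self.condition < 0) | (self.condition >= self.n_conditions)):
                raise ValueError("condition code out of range")
        else:
            raise ValueError(f"unknown series kind {self.kind!r}")

    def __len__(self) -> int:
        if self.kind == "poisson":
            return len(self.counts)
        return len(self.rt)


@dataclass
class SimulationRecord:
    """One simulated tuple (eta, theta_{0:T}, x_{1:T}) plus its seed."""

    eta: HighLevelParams
    trajectory: ParameterTrajectory
    series: ObservationSeries
    seed: int
    model_name: str = "model"


# ---------------------------------------------------------------------------
# prior sampling
# ---------------------------------------------------------------------------


def sample_prior(
    low: LowLevelSpec, transition: TransitionSpec, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` joint prior samples of (theta_0, eta).

    Returns ``(theta0, eta)`` with shapes ``(n, d)`` and ``(n, k)``, both on
    the natural scale.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    theta0 = np.column_stack(
        [low.theta0_priors[name].sample(n, rng) for name in low.param_names]
    )
    if transition.eta_dim:
        eta = np.column_stack(
            [transition.eta_priors[name].sample(n, rng) for name in transition.eta_names]
        )
    else:
        eta = np.empty((n, 0))
    return theta0, eta


# ---------------------------------------------------------------------------
# transition kernels (pure functions on the unconstrained scale)
# ---------------------------------------------------------------------------


def transition_random_walk(
    theta_prev: np.ndarray, sigma: np.ndarray, xi: np.ndarray
) -> np.ndarray:
    """Gaussian random walk step: ``theta_prev + sigma * xi``."""
    theta_prev = np.asarray(theta_prev, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if not theta_prev.shape == sigma.shape == xi.shape:
        raise ValueError("theta_prev, sigma and xi must have equal shapes")
    if np.any(sigma < 0):
        raise ValueError("random-walk scales must be non-negative")
    return theta_prev + sigma * xi


def transition_var(
    theta_hist: np.ndarray,
    c: np.ndarray,
    coeffs: list[np.ndarray],
    xi: np.ndarray,
) -> np.ndarray:
    """VAR(p) step: ``c + sum_k A_k theta_{t-k} + xi``.

    ``theta_hist`` holds the last ``p`` rows, most recent first
    (``theta_hist[0]`` is theta_{t-1}).  ``xi`` is the realized noise term.
    """
    theta_hist = np.atleast_2d(np.asarray(theta_hist, dtype=float))
    c = np.asarray(c, dtype=float)
    p = len(coeffs)
    if theta_hist.shape[0] < p:
        raise ValueError(f"need at least p={p} history rows")
    d = theta_hist.shape[1]
    out = c.copy()
    for k, A in enumerate(coeffs):
        A = np.asarray(A, dtype=float)
        if A.shape != (d, d):
            raise ValueError(f"A_{k + 1} has shape {A.shape}, expected {(d, d)}")
        out = out + A @ theta_hist[k]
    return out + np.asarray(xi, dtype=float)


def gp_kernel(tgrid: np.ndarray, sigma: float, ell: float) -> np.ndarray:
    """Squared-exponential covariance k(t,t') = sigma^2 exp(-(t-t')^2/(2 l^2))."""
    if ell <= 0:
        raise ValueError("GP length-scale must be positive")
    if sigma < 0:
        raise ValueError("GP amplitude must be non-negative")
    diff = tgrid[:, None] - tgrid[None, :]
    return sigma**2 * np.exp(-0.5 * (diff / ell) ** 2)


def sample_gp_trajectory(
    T: int,
    sigmas: np.ndarray,
    ells: np.ndarray,
    mean: np.ndarray,
    rng: np.random.Generator,
    pin_start: bool = False,
    jitter: float = 1e-6,
) -> np.ndarray:
    """Draw per-parameter independent GP paths over a normalized time grid.

    Returns a ``(T+1, d)`` matrix.  The time grid is ``linspace(0, 1, T+1)``
    so length-scales are comparable across series lengths.  With
    ``pin_start`` the path is conditioned to equal ``mean`` exactly at t=0
    (used by the simulator so that row 0 is the theta_0 prior draw).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    mean = np.asarray(mean, dtype=float)
    d = mean.shape[0]
    tgrid = np.linspace(0.0, 1.0, T + 1)
    out = np.empty((T + 1, d))
    for j in range(d):
        if sigmas[j] == 0.0:
            out[:, j] = mean[j]
            continue
        K = gp_kernel(tgrid, float(sigmas[j]), float(ells[j]))
        if pin_start:
            # condition the zero-mean GP on f(0) = 0
            k00 = K[0, 0] + jitter
            K = K - np.outer(K[:, 0], K[0, :]) / k00
        K[np.diag_indices_from(K)] += jitter
        L = np.linalg.cholesky(K)
        out[:, j] = mean[j] + L @ rng.standard_normal(T + 1)
        if pin_start:
            out[0, j] = mean[j]
    return out


def transition_regime_switch(
    theta_prev: np.ndarray,
    t: int,
    switch_times: tuple[int, ...],
    jump_bounds: list[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Piecewise-constant transition: uniform re-draw at switch times."""
    theta_prev = np.asarray(theta_prev, dtype=float)
    if t in switch_times:
        return np.array([rng.uniform(lo, hi) for lo, hi in jump_bounds])
    return theta_prev.copy()


def transition_itv(
    mean_row: np.ndarray, scales: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Memoryless inter-trial variability: independent N(mean, scales) draw."""
    mean_row = np.asarray(mean_row, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if np.any(scales < 0):
        raise ValueError("itv scales must be non-negative")
    return mean_row + scales * rng.standard_normal(mean_row.shape)


# ---------------------------------------------------------------------------
# trajectory + dataset simulation
# ---------------------------------------------------------------------------


def _eta_subvector(eta: HighLevelParams, prefix: str, names) -> np.ndarray:
    return np.array([eta[f"{prefix}{n}"] for n in names])


def simulate_trajectory(
    model: ModelSpec,
    eta: HighLevelParams,
    theta0: np.ndarray,
    T: int,
    rng: np.random.Generator,
) -> ParameterTrajectory:
    """Roll the declared transition model forward from theta_0 for T steps."""
    low, trans = model.low, model.transition
    d = low.dim
    names = low.param_names
    kind = trans.kind
    theta0 = np.asarray(theta0, dtype=float)

    if kind == "regime_switch":
        for st in trans.switch_times:
            if st >= T:
                raise ConfigurationError(f"switch time {st} >= series length {T}")
        bounds = [trans.jump_bounds[n] for n in names]
        vals = np.empty((T + 1, d))
        vals[0] = theta0
        for t in range(1, T + 1):
            vals[t] = transition_regime_switch(
                vals[t - 1], t, trans.switch_times, bounds, rng
            )
        return ParameterTrajectory(vals, names)

    u0 = low.to_unconstrained(theta0)
    if kind == "static":
        u = np.tile(u0, (T + 1, 1))
    elif kind == "random_walk":
        sigma = _eta_subvector(eta, "sigma_", names)
        incr = sigma * rng.standard_normal((T, d))
        u = np.vstack([u0, u0 + np.cumsum(incr, axis=0)])
    elif kind == "itv":
        scales = _eta_subvector(eta, "scale_", names)
        u = np.empty((T + 1, d))
        u[0] = u0
        for t in range(1, T + 1):
            u[t] = transition_itv(u0, scales, rng)
    elif kind == "gp":
        sigmas = _eta_subvector(eta, "sigma_", names)
        ells = _eta_subvector(eta, "ell_", names)
        u = sample_gp_trajectory(T, sigmas, ells, u0, rng, pin_start=True)
    elif kind == "var":
        c = _eta_subvector(eta, "c_", names)
        sigma = _eta_subvector(eta, "sigma_", names)
        coeffs = [
            np.diag(_eta_subvector(eta, f"A{k}_", names))
            for k in range(1, trans.var_order + 1)
        ]
        u = np.empty((T + 1, d))
        u[0] = u0
        for t in range(1, T + 1):
            hist = u[max(0, t - trans.var_order):t][::-1]
            if hist.shape[0] < trans.var_order:  # pad early history with u0
                pad = np.tile(u0, (trans.var_order - hist.shape[0], 1))
                hist = np.vstack([hist, pad])
            xi = sigma * rng.standard_normal(d)
            u[t] = transition_var(hist, c, coeffs, xi)
    else:  # pragma: no cover
        raise AssertionError(kind)
    return ParameterTrajectory(model.low.to_natural(u), names)


def _observe_poisson(traj: ParameterTrajectory, rng: np.random.Generator) -> ObservationSeries:
    lam = np.maximum(traj.values[1:, 0], _RATE_FLOOR)
    return ObservationSeries(kind="poisson", counts=rng.poisson(lam))


def _observe_ddm(
    low: LowLevelSpec,
    traj: ParameterTrajectory,
    rng: np.random.Generator,
    conditions: np.ndarray | None = None,
    dt: float = 1e-3,
    t_max: float = 10.0,
) -> ObservationSeries:
    from .observation import simulate_ddm_trials

    T = traj.T
    C = low.n_conditions
    if conditions is None:
        conditions = rng.integers(0, C, size=T)
    conditions = np.asarray(conditions, dtype=int)
    if np.any((conditions < 0) | (conditions >= C)):
        raise ValueError("condition code out of range")
    names = list(low.param_names)
    v_cols = [names.index(n) for n in names if n.startswith("v")]
    a_col, tau_col = names.index("a"), names.index("tau")
    th = traj.values[1:]
    v = th[np.arange(T), np.array(v_cols)[conditions]]
    a = th[:, a_col]
    tau = th[:, tau_col]
    seed = int(rng.integers(0, 2**31 - 1))
    rt, choice, timeout = simulate_ddm_trials(v, a, tau, dt=dt, t_max=t_max, seed=seed)
    return ObservationSeries(
        kind="ddm", rt=rt, choice=choice, condition=conditions,
        timeout=timeout, n_conditions=C,
    )


def simulate_dataset(
    model: ModelSpec,
    T: int,
    seed: int,
    conditions: np.ndarray | None = None,
    dt: float = 1e-3,
    t_max: float = 10.0,
) -> SimulationRecord:
    """Simulate a full tuple (eta, theta_{0:T}, x_{1:T}) from the model.

    The seed is split into independent prior / transition / observation
    substreams, so the observation noise stream does not depend on how many
    draws the transition consumed.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    ss = np.random.SeedSequence(seed)
    prior_rng, trans_rng, obs_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    low, trans = model.low, model.transition
    theta0 = np.array(
        [low.theta0_priors[n].sample(1, prior_rng)[0] for n in low.param_names]
    )
    eta_vals = np.array(
        [trans.eta_priors[n].sample(1, prior_rng)[0] for n in trans.eta_names]
    )
    eta = HighLevelParams(trans.eta_names, eta_vals)
    traj = simulate_trajectory(model, eta, theta0, T, trans_rng)
    if low.kind == "poisson":
        series = _observe_poisson(traj, obs_rng)
    else:
        series = _observe_ddm(low, traj, obs_rng, conditions, dt=dt, t_max=t_max)
    return SimulationRecord(eta, traj, series, seed, model.name)


# ---------------------------------------------------------------------------
# packaged model presets
# ---------------------------------------------------------------------------


def poisson_random_walk_model() -> ModelSpec:
    """Poisson counts with a Gaussian random walk on the rate.

    Priors follow the coal-mining benchmark: ``lambda_0 ~ Exp(0.5)`` and
    random-walk scale ``sigma ~ Beta(1, 25)``.
    """
    low = LowLevelSpec(
        kind="poisson",
        param_names=("lam",),
        theta0_priors={"lam": PriorSpec("exponential", {"rate": 0.5}, name="lam")},
        transforms={"lam": "identity"},
        bounds={"lam": (_RATE_FLOOR, np.inf)},
    )
    trans = TransitionSpec(
        kind="random_walk",
        eta_priors={"sigma_lam": PriorSpec("beta", {"a": 1, "b": 25}, name="sigma_lam")},
    )
    return ModelSpec(low, trans, name="poisson_random_walk")


def _ddm_low(n_conditions: int) -> LowLevelSpec:
    if n_conditions == 1:
        drift_names = ("v",)
    else:
        drift_names = tuple(f"v{c + 1}" for c in range(n_conditions))
    names = drift_names + ("a", "tau")
    priors: dict[str, PriorSpec] = {
        n: PriorSpec("normal", {"loc": 0.0, "scale": 2.5}, name=n) for n in drift_names
    }
    priors["a"] = PriorSpec("gamma", {"shape": 4.0, "rate": 3.0}, name="a")
    priors["tau"] = PriorSpec("gamma", {"shape": 1.5, "rate": 5.0}, name="tau")
    transforms = {n: "identity" for n in drift_names}
    transforms.update({"a": "log", "tau": "log"})
    bounds: dict[str, tuple[float, float]] = {n: (-np.inf, np.inf) for n in drift_names}
    # hard support: thresholds above ~10 evidence units or non-decision times
    # above ~5 s are outside any plausible two-choice experiment
    bounds.update({"a": (1e-3, 10.0), "tau": (1e-3, 5.0)})
    return LowLevelSpec(
        kind="ddm",
        param_names=names,
        theta0_priors=priors,
        transforms=transforms,
        bounds=bounds,
        n_conditions=n_conditions,
    )


def ddm_model(
    transition: str = "random_walk",
    n_conditions: int = 1,
    switch_times: tuple[int, ...] = (100, 200, 300),
) -> ModelSpec:
    """Non-stationary DDM presets used throughout the package.

    ``transition`` selects the high-level model: ``static``, ``random_walk``
    (scales ``sigma_k ~ Beta(1, 25)`` on the transformed scale), ``itv``
    (memoryless fluctuation, same scale prior), ``gp`` (squared-exponential
    kernel; amplitude ``~ Exp(4)``, length-scale ``~ U(0.05, 0.5)`` on the
    normalized time grid), or ``regime_switch`` (uniform jumps at
    ``switch_times``).
    """
    low = _ddm_low(n_conditions)
    names = low.param_names
    if transition == "static":
        trans = TransitionSpec(kind="static")
    elif transition == "random_walk":
        trans = TransitionSpec(
            kind="random_walk",
            eta_priors={
                f"sigma_{n}": PriorSpec("beta", {"a": 1, "b": 25}, name=f"sigma_{n}")
                for n in names
            },
        )
    elif transition == "itv":
        trans = TransitionSpec(
            kind="itv",
            eta_priors={
                f"scale_{n}": PriorSpec("beta", {"a": 1, "b": 25}, name=f"scale_{n}")
                for n in names
            },
        )
    elif transition == "gp":
        eta_priors: dict[str, PriorSpec] = {}
        for n in names:
            eta_priors[f"sigma_{n}"] = PriorSpec(
                "exponential", {"rate": 4.0}, name=f"sigma_{n}"
            )
            eta_priors[f"ell_{n}"] = PriorSpec(
                "uniform", {"lower": 0.05, "upper": 0.5}, name=f"ell_{n}"
            )
        trans = TransitionSpec(kind="gp", eta_priors=eta_priors)
    elif transition == "regime_switch":
        jump_bounds: dict[str, tuple[float, float]] = {}
        for n in names:
            if n.startswith("v"):
                jump_bounds[n] = (-4.0, 4.0)
            elif n == "a":
                jump_bounds[n] = (0.5, 3.0)
            else:
                jump_bounds[n] = (0.1, 1.0)
        trans = TransitionSpec(
            kind="regime_switch", switch_times=switch_times, jump_bounds=jump_bounds
        )
    else:
        raise ConfigurationError(f"unknown DDM transition preset {transition!r}")
    return ModelSpec(low, trans, name=f"ddm_{transition}")
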