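"""Lattice-based Bayesian filtering for the Poisson + random-walk model.

This is the low-dimensional exact(-to-resolution) filter: the rate parameter
``lambda`` lives on an equally spaced lattice, the random-walk transition is
applied as a Gaussian convolution of the probability mass (truncated at the
lattice edges and renormalized), and each count multiplies the mass by the
Poisson likelihood.  A second lattice over the random-walk scale ``sigma``
carries one filter per grid point; the accumulated log evidence per sigma
yields the marginal posterior over sigma, and the reported filtering
mean/SD of ``lambda_t`` marginalizes over it.

The filter serves as the independent oracle for the amortized neural method
on this model; with ``sigma = 0`` it reduces to conjugate Gamma–Poisson
updating, which anchors its correctness tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .priors import PriorSpec

__all__ = ["GridDensity", "HyperGrid", "GridFilterResult",
           "grid_predict", "grid_update", "grid_filter_run"]


def _poisson_loglik(x: int, lam: np.ndarray) -> np.ndarray:
    lam = np.maximum(lam, 1e-300)
    return x * np.log(lam) - lam - gammaln(x + 1.0)


@dataclass
class GridDensity:
    """Probability mass over an equally spaced 1-D lattice of rate values."""

    grid: np.ndarray
    log_mass: np.ndarray
    log_evidence: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.log_mass = np.asarray(self.log_mass, dtype=float)
        if self.grid.shape != self.log_mass.shape:
            raise ValueError("grid and mass shapes differ")

    @classmethod
    def from_prior(cls, grid: np.ndarray, prior: PriorSpec) -> "GridDensity":
        with np.errstate(divide="ignore"):
            lp = prior.logpdf(grid)
        lp = lp - logsumexp(lp)
        return cls(grid, lp)

    @property
    def spacing(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def mass(self) -> np.ndarray:
        return np.exp(self.log_mass - logsumexp(self.log_mass))

    @property
    def mean(self) -> float:
        return float(np.sum(self.mass * self.grid))

    @property
    def sd(self) -> float:
        m = self.mean
        return float(np.sqrt(max(np.sum(self.mass * self.grid**2) - m * m, 0.0)))


def _gaussian_kernel(sigma: float, h: float) -> np.ndarray:
    """Discrete Gaussian step kernel on a lattice with spacing h.

    For well-resolved scales (sigma >= 2h) the kernel samples the Gaussian
    density, which is spectrally exact.  Sub-lattice scales use
    variance-matched surrogates — a three-point kernel for sigma <= h, and
    CDF differences with a bin-width variance correction in between — so the
    per-step diffusion has the exact second moment at any resolution.
    """
    if sigma >= 2.0 * h:
        radius = int(np.ceil(6.0 * sigma / h))
        offsets = np.arange(-radius, radius + 1) * h
        k = np.exp(-0.5 * (offsets / sigma) ** 2)
    elif sigma <= h:
        p = 0.5 * (sigma / h) ** 2
        k = np.array([p, 1.0 - 2.0 * p, p])
    else:
        var = sigma**2 - h**2 / 12.0  # CDF binning adds h^2/12 of variance
        s = np.sqrt(var)
        radius = max(int(np.ceil(6.0 * s / h)), 1)
        offsets = np.arange(-radius, radius + 1) * h
        k = stats.norm.cdf((offsets + h / 2) / s) - stats.norm.cdf(
            (offsets - h / 2) / s
        )
    return k / k.sum()


def grid_predict(post: GridDensity, sigma: float) -> GridDensity:
    """Propagate the mass one step under the Gaussian random walk.

    Truncates at the lattice edges and renormalizes (mass never reflects).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        return GridDensity(post.grid, post.log_mass.copy(), post.log_evidence)
    h = post.spacing
    span = post.grid[-1] - post.grid[0]
    if 6.0 * sigma > 10.0 * span:
        warnings.warn("random-walk scale far exceeds the lattice range")
    kernel = _gaussian_kernel(sigma, h)
    mass = np.convolve(post.mass, kernel, mode="same")
    total = mass.sum()
    with np.errstate(divide="ignore"):
        log_mass = np.log(np.maximum(mass / total, 1e-300))
    return GridDensity(post.grid, log_mass, post.log_evidence)


def grid_update(prior: GridDensity, x: int) -> tuple[GridDensity, float]:
    """Multiply by the Poisson likelihood; returns posterior and the
    log-evidence increment (log normalizer), accumulated on the density."""
    if x < 0:
        raise ValueError("count must be non-negative")
    lp = prior.log_mass + _poisson_loglik(int(x), prior.grid)
    inc = float(logsumexp(lp))
    if not np.isfinite(inc):
        raise FloatingPointError("posterior mass degenerate after update")
    return GridDensity(prior.grid, lp - inc, prior.log_evidence + inc), inc


@dataclass
class HyperGrid:
    """One lattice filter per sigma grid point, plus the sigma posterior."""

    sigma_grid: np.ndarray
    densities: list[GridDensity]
    log_evidence: np.ndarray
    sigma_log_prior: np.ndarray

    @property
    def sigma_posterior(self) -> np.ndarray:
        lw = self.sigma_log_prior + self.log_evidence
        return np.exp(lw - logsumexp(lw))


@dataclass
class GridFilterResult:
    """Filtering summaries: per-step marginal mean/SD of the rate and the
    posterior over the random-walk scale."""

    mean: np.ndarray
    sd: np.ndarray
    hyper: HyperGrid
    log_evidence: float = 0.0
    # per-sigma per-step summaries kept for diagnostics
    _per_sigma_mean: np.ndarray = field(default=None, repr=False)

    @property
    def sigma_grid(self) -> np.ndarray:
        return self.hyper.sigma_grid

    @property
    def sigma_posterior(self) -> np.ndarray:
        return self.hyper.sigma_posterior


def grid_filter_run(
    counts: np.ndarray,
    lam_grid: np.ndarray | tuple[float, float, int] = (0.0, 15.0, 200),
    sigma_grid: np.ndarray | tuple[float, float, int] = (0.0, 1.0, 40),
    lam_prior: PriorSpec | None = None,
    sigma_prior: PriorSpec | None = None,
) -> GridFilterResult:
    """Run the full lattice filter over a count series.

    For every sigma lattice point an independent predict/update filter runs
    over the series, accumulating log evidence.  The filtering mean/SD of
    ``lambda_t`` reported for step t marginalizes over sigma with weights
    proportional to ``prior(sigma) * evidence(sigma | x_{1:t})``.

    Defaults follow the coal-mining benchmark priors ``lambda_0 ~ Exp(0.5)``
    and ``sigma ~ Beta(1, 25)``; lattice resolutions default to a desk-scale
    200 x 40 (the benchmark's 4000-point lattice is a config choice).
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count series")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if isinstance(lam_grid, tuple):
        lam_grid = np.linspace(*lam_grid[:2], int(lam_grid[2]))
    if isinstance(sigma_grid, tuple):
        sigma_grid = np.linspace(*sigma_grid[:2], int(sigma_grid[2]))
    lam_prior = lam_prior or PriorSpec("exponential", {"rate": 0.5}, name="lam0")
    sigma_prior = sigma_prior or PriorSpec("beta", {"a": 1, "b": 25}, name="sigma")

    T = len(counts)
    S = len(sigma_grid)
    with np.errstate(divide="ignore"):
        sig_lp = sigma_prior.logpdf(sigma_grid)
    sig_lp = sig_lp - logsumexp(sig_lp)

    per_mean = np.empty((S, T))
    per_m2 = np.empty((S, T))
    per_ev = np.empty((S, T))  # cumulative log evidence up to t
    finals: list[GridDensity] = []
    for j, sig in enumerate(sigma_grid):
        dens = GridDensity.from_prior(lam_grid, lam_prior)
        kernel = _gaussian_kernel(float(sig), dens.spacing) if sig > 0 else None
        cum = 0.0
        for t in range(T):
            if kernel is not None:
                mass = np.convolve(dens.mass, kernel, mode="same")
                mass /= mass.sum()
                with np.errstate(divide="ignore"):
                    dens = GridDensity(lam_grid, np.log(np.maximum(mass, 1e-300)), cum)
            dens, inc = grid_update(dens, int(counts[t]))
            cum += inc
            m = dens.mean
            per_mean[j, t] = m
            per_m2[j, t] = m * m + dens.sd**2
            per_ev[j, t] = cum
        finals.append(dens)

    # per-step sigma weights and marginal moments
    lw = sig_lp[:, None] + per_ev  # (S, T)
    w = np.exp(lw - logsumexp(lw, axis=0, keepdims=True))
    mean = np.sum(w * per_mean, axis=0)
    second = np.sum(w * per_m2, axis=0)
    sd = np.sqrt(np.maximum(second - mean**2, 0.0))

    hyper = HyperGrid(sigma_grid, finals, per_ev[:, -1], sig_lp)
    total_ev = float(logsumexp(sig_lp + per_ev[:, -1]))
    return GridFilterResult(mean, sd, hyper, total_ev, per_mean)
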