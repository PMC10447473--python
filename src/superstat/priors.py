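"""Prior distribution descriptors for low- and high-level model parameters.

A :class:`PriorSpec` is a thin, serializable wrapper around a scipy frozen
distribution.  Supported families cover the priors used by the packaged
models: normal, truncated normal, gamma, exponential, beta and uniform.
Gamma and exponential are parameterized by *rate* (so ``gamma(4, 3)`` has
mean ``4/3`` and ``exponential(0.5)`` has mean ``2``), matching the common
convention in the Bayesian cognitive-modelling literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

__all__ = ["PriorSpec", "ConfigurationError"]


class ConfigurationError(ValueError):
    """A model/prior declaration is inconsistent or names an unknown family."""


_FAMILIES = ("normal", "truncated-normal", "gamma", "exponential", "beta", "uniform")


@dataclass
class PriorSpec:
    """Distribution descriptor for a single scalar parameter.

    Parameters
    ----------
    family:
        One of ``normal``, ``truncated-normal``, ``gamma``, ``exponential``,
        ``beta``, ``uniform``.
    params:
        Family-specific parameters:

        - normal: ``loc``, ``scale``
        - truncated-normal: ``loc``, ``scale`` (+ ``lower``/``upper`` bounds)
        - gamma: ``shape``, ``rate``
        - exponential: ``rate``
        - beta: ``a``, ``b``
        - uniform: ``lower``, ``upper``
    name:
        Optional parameter name, used in error messages.
    """

    family: str
    params: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown prior family {self.family!r} for parameter "
                f"{self.name or '<unnamed>'}; expected one of {_FAMILIES}"
            )
        try:
            self._frozen = self._freeze()
        except KeyError as exc:
            raise ConfigurationError(
                f"prior for parameter {self.name or '<unnamed>'} "
                f"({self.family}) is missing parameter {exc}"
            ) from None

    def _freeze(self):
        p = self.params
        if self.family == "normal":
            return stats.norm(loc=p["loc"], scale=p["scale"])
        if self.family == "truncated-normal":
            loc, scale = p["loc"], p["scale"]
            lo = p.get("lower", -np.inf)
            hi = p.get("upper", np.inf)
            a, b = (lo - loc) / scale, (hi - loc) / scale
            return stats.truncnorm(a, b, loc=loc, scale=scale)
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=1.0 / p["rate"])
        if self.family == "exponential":
            return stats.expon(scale=1.0 / p["rate"])
        if self.family == "beta":
            return stats.beta(p["a"], p["b"])
        if self.family == "uniform":
            lo, hi = p["lower"], p["upper"]
            if not hi > lo:
                raise ConfigurationError(
                    f"uniform prior for {self.name or '<unnamed>'} needs upper > lower"
                )
            return stats.uniform(loc=lo, scale=hi - lo)
        raise AssertionError(self.family)

    # -- support ----------------------------------------------------------
    @property
    def support(self) -> tuple[float, float]:
        lo, hi = self._frozen.support()
        return float(lo), float(hi)

    # -- sampling / density ------------------------------------------------
    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 0:
            raise ValueError("n must be >= 0")
        return np.asarray(self._frozen.rvs(size=n, random_state=rng))

    def logpdf(self, x: Any) -> np.ndarray:
        return np.asarray(self._frozen.logpdf(x))

    def pdf(self, x: Any) -> np.ndarray:
        return np.asarray(self._frozen.pdf(x))

    @property
    def mean(self) -> float:
        return float(self._frozen.mean())

    @property
    def sd(self) -> float:
        return float(self._frozen.std())

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params), "name": self.name}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(family=d["family"], params=dict(d["params"]), name=d.get("name", ""))
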