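"""Additive-noise distributions for data generation and GoF reference.

Four families are supported: Gaussian, uniform, Poisson and gamma.  A
:class:`NoiseSpec` bundles the family with its parameters and exposes the
density (or probability mass), cumulative distribution, analytic mean and
seeded sampling.  The same object serves two roles: generating the additive
noise of a synthetic dataset, and acting as the fully specified reference
distribution of the goodness-of-fit tests.

The gamma family uses the shape-scale parameterisation
``x**(k-1) * exp(-x/theta) / (theta**k * Gamma(k))``; the Poisson family is
discrete over the nonnegative integers and its ``pdf`` accessor returns the
probability mass function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import ParameterError

FAMILIES = ("gaussian", "uniform", "poisson", "gamma")

_REQUIRED_PARAMS = {
    "gaussian": ("mu", "sigma"),
    "uniform": ("a", "b"),
    "poisson": ("lam",),
    "gamma": ("k", "theta"),
}

# accept common aliases on input
_ALIASES = {"lambda": "lam", "mean": "mu", "std": "sigma", "shape": "k", "scale": "theta"}


@dataclass(frozen=True)
class NoiseSpec:
    """A noise family plus its parameters.

    Parameters
    ----------
    family : {"gaussian", "uniform", "poisson", "gamma"}
    params : mapping
        gaussian: ``mu``, ``sigma > 0``; uniform: ``a < b``;
        poisson: ``lam > 0``; gamma: ``k > 0``, ``theta > 0``.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown noise family {self.family!r}")
        clean = {}
        for name, value in dict(self.params).items():
            clean[_ALIASES.get(name, name)] = float(value)
        missing = [p for p in _REQUIRED_PARAMS[self.family] if p not in clean]
        if missing:
            raise ParameterError(
                f"{self.family} noise requires parameters {missing}"
            )
        object.__setattr__(self, "params", clean)
        self._validate()

    def _validate(self):
        p = self.params
        if self.family == "gaussian" and p["sigma"] <= 0:
            raise ParameterError("gaussian sigma must be > 0")
        if self.family == "uniform" and p["a"] >= p["b"]:
            raise ParameterError("uniform requires a < b")
        if self.family == "poisson" and p["lam"] <= 0:
            raise ParameterError("poisson lambda must be > 0")
        if self.family == "gamma" and (p["k"] <= 0 or p["theta"] <= 0):
            raise ParameterError("gamma shape and scale must be > 0")

    # -- constructors ----------------------------------------------------
    @classmethod
    def gaussian(cls, mu: float = 0.0, sigma: float = 3.0) -> "NoiseSpec":
        return cls("gaussian", {"mu": mu, "sigma": sigma})

    @classmethod
    def uniform(cls, a: float = -1.0, b: float = 1.0) -> "NoiseSpec":
        return cls("uniform", {"a": a, "b": b})

    @classmethod
    def poisson(cls, lam: float = 10.0) -> "NoiseSpec":
        return cls("poisson", {"lam": lam})

    @classmethod
    def gamma(cls, k: float = 3.0, theta: float = 2.0) -> "NoiseSpec":
        return cls("gamma", {"k": k, "theta": theta})

    # -- behaviour -------------------------------------------------------
    @property
    def discrete(self) -> bool:
        return self.family == "poisson"

    def dist(self):
        """The frozen scipy distribution matching this spec."""
        p = self.params
        if self.family == "gaussian":
            return stats.norm(loc=p["mu"], scale=p["sigma"])
        if self.family == "uniform":
            return stats.uniform(loc=p["a"], scale=p["b"] - p["a"])
        if self.family == "poisson":
            return stats.poisson(p["lam"])
        return stats.gamma(p["k"], scale=p["theta"])

    def mean(self) -> float:
        p = self.params
        return {
            "gaussian": lambda: p["mu"],
            "uniform": lambda: 0.5 * (p["a"] + p["b"]),
            "poisson": lambda: p["lam"],
            "gamma": lambda: p["k"] * p["theta"],
        }[self.family]()

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. values using an existing generator."""
        if n < 1:
            raise ValueError("sample size must be >= 1")
        p = self.params
        if self.family == "gaussian":
            return rng.normal(p["mu"], p["sigma"], n)
        if self.family == "uniform":
            return rng.uniform(p["a"], p["b"], n)
        if self.family == "poisson":
            return rng.poisson(p["lam"], n).astype(float)
        return rng.gamma(p["k"], p["theta"], n)

    # -- serialisation ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"family": self.family, "params": dict(self.params)})

    @classmethod
    def from_json(cls, text: str) -> "NoiseSpec":
        obj = json.loads(text)
        return cls(obj["family"], obj.get("params", {}))


def noise_pdf(spec: NoiseSpec, x) -> np.ndarray | float:
    """Density at ``x`` (probability mass for the discrete Poisson family).

    Nonnegative everywhere and zero outside the support; for Poisson,
    non-integer ``x`` has mass zero.
    """
    d = spec.dist()
    out = d.pmf(x) if spec.discrete else d.pdf(x)
    return float(out) if np.isscalar(x) else np.asarray(out)


def noise_cdf(spec: NoiseSpec, x) -> np.ndarray | float:
    """Cumulative distribution at ``x`` (right-continuous step for Poisson)."""
    out = spec.dist().cdf(x)
    return float(out) if np.isscalar(x) else np.asarray(out)


def noise_sample(spec: NoiseSpec, n: int, seed: int) -> np.ndarray:
    """``n`` i.i.d. draws, deterministic given ``seed`` (no global state)."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    return spec.sample(n, np.random.default_rng(seed))


def noise_mean(spec: NoiseSpec) -> float:
    """Analytic mean: mu, (a+b)/2, lambda, or k*theta."""
    return spec.mean()
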