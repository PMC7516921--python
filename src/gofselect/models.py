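"""Model families, evaluation, residuals and least-squares fitting.

Three parametric families of bivariate surfaces ``z = f(x, y)`` are
supported, chosen because they cover most empirical modelling practice:

* ``exponential``: ``a x e^(b x + c y) + d x e^(e x + f y) + g`` (7 params)
* ``polynomial``:  ``p00 + p10 x + p20 x^2 + p01 y + p02 y^2 + p03 y^3
  + p11 x y + p21 x^2 y + p12 x y^2`` (9 params, linear in parameters)
* ``power_law``:   ``c x^a y^b`` (3 params; exponents may be negative)

A ``custom`` family wraps an arbitrary callable and is used for the
benchmark's generating functions.  Fitting minimises the plain sum of
squared residuals: the polynomial family is solved in closed form, the
nonlinear families by damped (trust-region) least squares; the power law is
fitted in the original space — not log-linearised — to stay consistent
with an additive-noise error model, with a multi-start sign/scale grid
guarding against local minima.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConvergenceError, ParameterError
from .noise import NoiseSpec

EXPONENTIAL_PARAMS = ("a", "b", "c", "d", "e", "f", "g")
POLYNOMIAL_PARAMS = ("p00", "p10", "p20", "p01", "p02", "p03", "p11", "p21", "p12")
POWER_LAW_PARAMS = ("c", "a", "b")

_FAMILY_PARAMS = {
    "exponential": EXPONENTIAL_PARAMS,
    "polynomial": POLYNOMIAL_PARAMS,
    "power_law": POWER_LAW_PARAMS,
}


@dataclass(frozen=True)
class ModelSpec:
    """A model family with a concrete parameter vector.

    ``k`` is the parameter count entering the criteria penalties; it
    defaults to the length of the parameter vector but may be overridden
    (e.g. for a generating function whose only free constant is a scale).
    """

    family: str
    parameters: Mapping[str, float] = field(default_factory=dict)
    k: Optional[int] = None
    label: str = "model"
    func: Optional[Callable] = None
    converged: Optional[bool] = None

    def __post_init__(self):
        if self.family in _FAMILY_PARAMS:
            names = _FAMILY_PARAMS[self.family]
            missing = [p for p in names if p not in self.parameters]
            if missing:
                raise ParameterError(
                    f"{self.family} model missing parameters {missing}"
                )
            object.__setattr__(
                self, "parameters",
                {p: float(self.parameters[p]) for p in names},
            )
        elif self.family == "custom":
            if self.func is None:
                raise ParameterError("custom model requires a callable func")
            object.__setattr__(
                self, "parameters",
                {p: float(v) for p, v in dict(self.parameters).items()},
            )
        else:
            raise ParameterError(f"unknown model family {self.family!r}")
        if self.k is None:
            object.__setattr__(self, "k", len(self.parameters))

    @property
    def theta(self) -> np.ndarray:
        return np.array(list(self.parameters.values()), dtype=float)

    def __call__(self, x, y):
        return evaluate_model(self, x, y)

    def to_json(self) -> str:
        return json.dumps({
            "family": self.family,
            "parameters": dict(self.parameters),
            "k": self.k,
            "label": self.label,
            "converged": self.converged,
        })

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        obj = json.loads(text)
        return cls(
            family=obj["family"], parameters=obj["parameters"],
            k=obj.get("k"), label=obj.get("label", "model"),
            converged=obj.get("converged"),
        )


@dataclass(frozen=True)
class Dataset:
    """Paired covariates (x, y) and response z, with optional provenance."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.x.shape == self.y.shape == self.z.shape) or self.x.ndim != 1:
            raise ValueError("x, y, z must be equal-length 1-D vectors")
        if self.x.size < 1:
            raise ValueError("dataset must contain at least one point")
        if not all(np.all(np.isfinite(v)) for v in (self.x, self.y, self.z)):
            raise ValueError("dataset contains non-finite values")

    def __len__(self) -> int:
        return self.x.size

    def to_csv(self, path) -> None:
        pd.DataFrame({"x": self.x, "y": self.y, "z": self.z}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        df = pd.read_csv(path)
        return cls(df["x"].to_numpy(), df["y"].to_numpy(), df["z"].to_numpy())


def _poly_design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([
        np.ones_like(x), x, x ** 2, y, y ** 2, y ** 3, x * y, x ** 2 * y, x * y ** 2,
    ])


def _eval_family(family: str, theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if family == "exponential":
        a, b, c, d, e, f, g = theta
        return a * x * np.exp(b * x + c * y) + d * x * np.exp(e * x + f * y) + g
    if family == "polynomial":
        return _poly_design(x, y) @ theta
    # power law; fractional exponents require positive bases
    cc, a, b = theta
    if (np.any(x <= 0) and a != round(a)) or (np.any(y <= 0) and b != round(b)):
        raise ValueError("power law with fractional exponent needs positive covariates")
    if np.any(y == 0) and b < 0:
        raise ValueError("power law with negative y-exponent undefined at y = 0")
    if np.any(x == 0) and a < 0:
        raise ValueError("power law with negative x-exponent undefined at x = 0")
    return cc * x ** a * y ** b


def evaluate_model(model: ModelSpec, x, y) -> np.ndarray:
    """Pointwise evaluation of the model surface at (x, y)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have the same shape")
    if model.family == "custom":
        out = np.asarray(model.func(xa, ya), dtype=float)
    else:
        out = _eval_family(model.family, model.theta, xa, ya)
    if not np.all(np.isfinite(out)):
        raise ValueError("model evaluation produced non-finite values")
    return out


def compute_residuals(model: ModelSpec, data: Dataset) -> np.ndarray:
    """Residuals ``z_i - model(x_i, y_i)``, order preserved."""
    return data.z - evaluate_model(model, data.x, data.y)


# ---------------------------------------------------------------------------
# fitting

def _power_law_starts(data: Dataset, seed: int) -> list[np.ndarray]:
    """Sign/scale grid of 8 starts; a log-regression start is prepended
    when the data allow it (all x, y, z positive)."""
    rng = np.random.default_rng(seed)
    zscale = float(np.median(np.abs(data.z))) or 1.0
    starts = []
    if np.all(data.x > 0) and np.all(data.y > 0) and np.all(data.z > 0):
        A = np.column_stack([np.ones_like(data.x), np.log(data.x), np.log(data.y)])
        coef, *_ = np.linalg.lstsq(A, np.log(data.z), rcond=None)
        starts.append(np.array([math.exp(coef[0]), coef[1], coef[2]]))
    for a0 in (1.0, 2.0):
        for b0 in (1.0, -1.0):
            for c0 in (zscale, -zscale):
                jitter = rng.uniform(-0.25, 0.25, 3)
                starts.append(np.array([c0, a0, b0]) + jitter)
    return starts


def _exponential_starts(data: Dataset, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    zbar = float(np.mean(data.z))
    zscale = float(np.std(data.z)) or 1.0
    base = np.array([1.0, -0.5, 0.1, 1.0, -1.0, -0.1, zbar])
    starts = [base]
    for _ in range(7):
        amp = rng.choice([1.0, zscale / 10, zscale]) * rng.choice([-1.0, 1.0])
        rates = rng.uniform(-1.5, 0.5, 4)
        starts.append(np.array([
            amp, rates[0], rates[1],
            amp * rng.uniform(-1, 1), rates[2], rates[3], zbar,
        ]))
    return starts


def fit_model(family: str, data: Dataset,
              init: Optional[Sequence[float]] = None,
              max_iter: int = 1000, tol: float = 1e-12,
              seed: int = 0, label: str = "Alternative") -> ModelSpec:
    """Least-squares fit of one family to a dataset.

    Polynomial fits are solved exactly (linear in parameters); exponential
    and power-law fits run damped least squares from either the supplied
    ``init`` or a seeded multi-start grid, keeping the start with the
    lowest sum of squared residuals.  Deterministic given (data, init,
    seed).
    """
    if family not in _FAMILY_PARAMS:
        raise ParameterError(f"cannot fit family {family!r}")
    names = _FAMILY_PARAMS[family]
    if len(data) <= len(names):
        raise ValueError(
            f"need more than {len(names)} points to fit {family}"
        )

    if family == "polynomial":
        A = _poly_design(data.x, data.y)
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient polynomial design matrix")
        theta, *_ = np.linalg.lstsq(A, data.z, rcond=None)
        return ModelSpec(family, dict(zip(names, theta)), label=label, converged=True)

    def resid(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            pred = _eval_family(family, theta, data.x, data.y)
        return np.nan_to_num(pred - data.z, nan=1e12, posinf=1e12, neginf=-1e12)

    if init is not None:
        starts = [np.asarray(init, dtype=float)]
    elif family == "power_law":
        starts = _power_law_starts(data, seed)
    else:
        starts = _exponential_starts(data, seed)

    best = None
    with np.errstate(over="ignore", invalid="ignore"):
        for x0 in starts:
            sol = least_squares(resid, x0, method="trf", max_nfev=max_iter,
                                xtol=tol, ftol=tol, gtol=tol)
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise ConvergenceError(f"{family} fit failed to converge",
                               last_iterate=None if best is None else best.x)
    converged = bool(best.status > 0)
    theta = best.x
    if family == "exponential":
        theta = _canonical_exponential(theta)
    return ModelSpec(family, dict(zip(names, theta)), label=label,
                     converged=converged)


def _canonical_exponential(theta: np.ndarray) -> np.ndarray:
    """Fix the two-term swap symmetry: order terms by (b, c, a)."""
    first, second, g = theta[:3], theta[3:6], theta[6]
    if tuple(second[[1, 2, 0]]) < tuple(first[[1, 2, 0]]):
        first, second = second, first
    return np.concatenate([first, second, [g]])


# ---------------------------------------------------------------------------
# benchmark generating functions

def generating_model(case: str, power_law_c: float = 1.0,
                     correct_k: Optional[int] = None) -> ModelSpec:
    """The data-generating surface for each benchmark case, labelled "Correct".

    ``k`` defaults to the number of free constants in the generating
    expression: 1 for the exponential case (the overall scale 100), 2 for
    the polynomial case (the two coefficients equal to 3), and 3 for the
    power-law case (which lies inside the fitted family).
    """
    if case == "exponential":
        return ModelSpec(
            "custom", {"scale": 100.0},
            k=1 if correct_k is None else correct_k, label="Correct",
            func=lambda x, y: 100.0 * (x + y) * np.exp(-x),
        )
    if case == "polynomial":
        return ModelSpec(
            "custom", {"c_x": 3.0, "c_y4": 3.0},
            k=2 if correct_k is None else correct_k, label="Correct",
            func=lambda x, y: 3.0 * x + x ** 2 + y + 3.0 * y ** 4,
        )
    if case == "power_law":
        return ModelSpec(
            "power_law", {"c": power_law_c, "a": 3.0, "b": -1.0},
            k=3 if correct_k is None else correct_k, label="Correct",
        )
    raise ParameterError(f"unknown benchmark case {case!r}")
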