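"""Model selection criteria built from residual statistics.

Six criteria are provided, all cost functions to be minimised, all using
natural logarithms:

* classic:  ``AIC = n ln(MSE) + 2k``, ``BIC = n ln(Var) + k ln n``
* entropy:  ``AIC_H = n ln(MSE / H) + 2k``, ``BIC_H = n ln(Var / H) + k ln n``
* GoF:      ``AIC_GF = n ln(MSE (1 + Z^2) / H) + 2k`` and the BIC analogue

where MSE is the mean of squared residuals, Var their population (1/n)
variance (so ``MSE = Var + mean^2`` exactly), H the Shannon entropy of the
binned residual distribution in nats, and Z a goodness-of-fit z-score of
the residuals against the known noise law.  Dividing by H rewards residual
histograms without leftover structure; the ``(1 + Z^2)`` factor inflates
the cost of residuals that do not look like the noise, and vanishes
(Z -> 0) for a perfect model as n grows, so the GF criteria converge to
the entropy ones.

A Gaussian likelihood form ``-2 ln L + penalty`` is also provided as an
oracle: with the ML variance plugged in it equals the classic AIC/BIC plus
the model-independent constant ``n (ln 2 pi + 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateFitError
from .gof import GofResult, gof_result
from .noise import NoiseSpec

CRITERIA = ("aic", "bic", "aic_h", "bic_h", "aic_gf", "bic_gf")


@dataclass(frozen=True)
class ResidualSummary:
    """Descriptive statistics of one residual vector.

    ``variance`` uses the population (1/n) convention, so
    ``mse == variance + mean**2`` holds exactly.  ``entropy`` is floored at
    ``1/n`` (``entropy_floored`` records whether the floor was applied).
    """

    n: int
    mean: float
    mse: float
    variance: float
    entropy: float
    entropy_floored: bool = False
    z_score: Optional[float] = None


def default_bin_count(n: int) -> int:
    """Histogram bin count used for the residual entropy: max(2, ceil(sqrt n))."""
    return max(2, math.ceil(math.sqrt(n)))


def _check_residuals(residuals) -> np.ndarray:
    arr = np.asarray(residuals, dtype=float)
    if arr.size == 0:
        raise ValueError("residuals must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("residuals contain non-finite values")
    return arr


def residual_entropy(residuals, n_bins: Optional[int] = None,
                     bin_edges: Optional[Sequence[float]] = None) -> float:
    """Shannon entropy (nats) of the binned residual distribution.

    ``H = -sum_i p_i ln p_i`` with ``p_i`` the fraction of residuals in bin
    i; empty bins contribute nothing.  The result is floored at ``1/n`` so
    that a degenerate single-bin histogram does not zero out the criteria
    it divides.  When comparing models, pass shared ``bin_edges`` so H is
    computed on identical bins for every candidate.
    """
    arr = _check_residuals(residuals)
    n = arr.size
    if bin_edges is not None:
        edges = np.asarray(bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if arr.min() < edges[0] or arr.max() > edges[-1]:
            raise ValueError("bin_edges must cover all residuals")
    else:
        b = n_bins if n_bins is not None else default_bin_count(n)
        lo, hi = float(arr.min()), float(arr.max())
        if lo == hi:  # all residuals identical: single occupied bin, H = 0
            return 1.0 / n
        edges = np.linspace(lo, hi, b + 1)
    counts, _ = np.histogram(arr, bins=edges)
    p = counts[counts > 0] / n
    h = float(-np.sum(p * np.log(p)))
    return max(h, 1.0 / n)


def summarize_residuals(residuals, ref: Optional[NoiseSpec] = None,
                        test: str = "ks", n_bins: Optional[int] = None,
                        bin_edges: Optional[Sequence[float]] = None,
                        zscore_mode: str = "statistic") -> ResidualSummary:
    """Compute the shared summary all six criteria are built from."""
    arr = _check_residuals(residuals)
    n = arr.size
    mean = float(arr.mean())
    mse = float(np.mean(arr ** 2))
    variance = float(np.var(arr))
    h = residual_entropy(arr, n_bins=n_bins, bin_edges=bin_edges)
    z = None
    if ref is not None:
        z = gof_result(arr, ref, test, zscore_mode=zscore_mode).z_score
    return ResidualSummary(
        n=n, mean=mean, mse=mse, variance=variance,
        entropy=h, entropy_floored=(h == 1.0 / n), z_score=z,
    )


def _spread(kind: str, summary: ResidualSummary) -> float:
    if kind not in ("aic", "bic"):
        raise ValueError("kind must be 'aic' or 'bic'")
    s = summary.mse if kind == "aic" else summary.variance
    if s <= 0:
        raise DegenerateFitError("residuals have zero spread")
    return s


def _penalty(kind: str, n: int, k: int) -> float:
    return 2.0 * k if kind == "aic" else k * math.log(n)


def classic_criterion(kind: str, summary: ResidualSummary, k: int) -> float:
    """Classic residual form: ``n ln(MSE) + 2k`` or ``n ln(Var) + k ln n``."""
    s = _spread(kind, summary)
    return summary.n * math.log(s) + _penalty(kind, summary.n, k)


def entropy_criterion(kind: str, summary: ResidualSummary, k: int) -> float:
    """Entropy-upgraded form: spread divided by the residual entropy H."""
    s = _spread(kind, summary)
    return summary.n * math.log(s / summary.entropy) + _penalty(kind, summary.n, k)


def gf_criterion(kind: str, summary: ResidualSummary, k: int) -> float:
    """GoF-upgraded form: spread scaled by ``(1 + Z^2) / H``."""
    if summary.z_score is None:
        raise ValueError("summary has no z_score; pass a reference noise spec")
    s = _spread(kind, summary)
    factor = (1.0 + summary.z_score ** 2) / summary.entropy
    return summary.n * math.log(s * factor) + _penalty(kind, summary.n, k)


def gaussian_loglik_criterion(kind: str, residuals, k: int) -> float:
    """Likelihood form ``-2 ln L + penalty`` under a Gaussian error model.

    The ML variance (the residual MSE) is plugged into the Gaussian
    log-likelihood, giving ``n (ln 2 pi + ln MSE + 1) + penalty``; it
    exceeds the classic criterion by the constant ``n (ln 2 pi + 1)``.
    """
    arr = _check_residuals(residuals)
    n = arr.size
    mse = float(np.mean(arr ** 2))
    if mse <= 0:
        raise DegenerateFitError("residuals have zero spread")
    minus2loglik = n * (math.log(2 * math.pi) + math.log(mse) + 1.0)
    return minus2loglik + _penalty(kind, n, k)


@dataclass(frozen=True)
class CriteriaTable:
    """All six criteria for one model, with the summary they share."""

    label: str
    k: int
    summary: ResidualSummary
    gof: Optional[GofResult]
    values: dict
    converged: Optional[bool] = None

    def best(self) -> str:
        return min(self.values, key=self.values.get)

    def to_frame(self) -> pd.DataFrame:
        s = self.summary
        rows = [
            {
                "model_label": self.label,
                "criterion": c,
                "value": v,
                "n": s.n,
                "k": self.k,
                "mse": s.mse,
                "variance": s.variance,
                "entropy": s.entropy,
                "z_score": s.z_score,
                "gof_test": self.gof.test if self.gof is not None else None,
            }
            for c, v in self.values.items()
        ]
        return pd.DataFrame(rows)


def criteria_table(residuals, k: int, ref: NoiseSpec, test: str = "ks",
                   n_bins: Optional[int] = None,
                   bin_edges: Optional[Sequence[float]] = None,
                   zscore_mode: str = "statistic",
                   label: str = "model") -> CriteriaTable:
    """Bundle all six criteria for one model's residuals.

    Deterministic given its inputs; the entropy and z-score are computed
    once and shared by every criterion.
    """
    arr = _check_residuals(residuals)
    gof = gof_result(arr, ref, test, zscore_mode=zscore_mode)
    h = residual_entropy(arr, n_bins=n_bins, bin_edges=bin_edges)
    summary = ResidualSummary(
        n=arr.size,
        mean=float(arr.mean()),
        mse=float(np.mean(arr ** 2)),
        variance=float(np.var(arr)),
        entropy=h,
        entropy_floored=(h == 1.0 / arr.size),
        z_score=gof.z_score,
    )
    values = {
        "aic": classic_criterion("aic", summary, k),
        "bic": classic_criterion("bic", summary, k),
        "aic_h": entropy_criterion("aic", summary, k),
        "bic_h": entropy_criterion("bic", summary, k),
        "aic_gf": gf_criterion("aic", summary, k),
        "bic_gf": gf_criterion("bic", summary, k),
    }
    return CriteriaTable(label=label, k=k, summary=summary, gof=gof, values=values)
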