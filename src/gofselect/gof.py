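"""Goodness-of-fit discrepancies between residuals and a known noise law.

Three classical tests are computed against a *fully specified* reference
distribution (the noise law is known, no parameters are estimated from the
sample): Kolmogorov-Smirnov, Anderson-Darling and Pearson chi-squared.

Each test is summarised by a nonnegative "Z score" that converges to zero
under the null as the sample grows:

* K-S: the raw sup-distance ``D_n`` (already in [0, 1] and O(n^-1/2) under
  the null),
* Anderson-Darling: ``A^2 / n`` (``A^2`` is O(1) under the null),
* chi-squared: ``chi2 / n`` (the statistic stays near its degrees of
  freedom under the null while n grows).

Under a fixed alternative all three z-scores stay bounded away from zero,
which is what lets them enter a selection criterion through a
``(1 + Z^2)`` inflation factor.  An alternative standardisation
``zscore_mode="pvalue"`` maps the test's p-value through the upper normal
quantile, ``Z = max(0, Phi^-1(1 - p))``; it is provided for sensitivity
analysis only (it does not vanish under the null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special, stats

from .errors import BinningError
from .noise import NoiseSpec

TESTS = ("ks", "anderson_darling", "chi_squared")

_AD_CLIP = 1e-12


@dataclass(frozen=True)
class GofResult:
    """Outcome of one goodness-of-fit test.

    ``statistic`` is the raw test statistic (D_n, A^2 or chi^2);
    ``z_score`` is the normalised discrepancy consumed by the selection
    criteria; ``df`` is set for chi-squared only.
    """

    test: str
    statistic: float
    z_score: float
    n: int
    df: Optional[int] = None


def _check_sample(sample) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise ValueError("sample must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample contains non-finite values")
    return arr


def ks_discrepancy(sample, ref: NoiseSpec) -> GofResult:
    """Kolmogorov-Smirnov sup-distance between the ECDF and the reference CDF.

    For a continuous reference, ``D_n = max(D+, D-)`` over the order
    statistics.  For a discrete (Poisson) reference the supremum is taken
    over the union of the integer support and the sample points, evaluating
    both one-sided ECDF limits against the step CDF.
    """
    arr = np.sort(_check_sample(sample))
    n = arr.size
    d = ref.dist()
    if not ref.discrete:
        u = d.cdf(arr)
        i = np.arange(1, n + 1)
        stat = max(np.max(i / n - u), np.max(u - (i - 1) / n))
    else:
        hi = max(math.ceil(arr[-1]), int(d.ppf(1 - 1e-12))) + 1
        lo = min(math.floor(arr[0]), 0)
        pts = np.union1d(arr, np.arange(lo, hi + 1, dtype=float))
        ecdf_right = np.searchsorted(arr, pts, side="right") / n
        ecdf_left = np.searchsorted(arr, pts, side="left") / n
        cdf_right = d.cdf(pts)
        cdf_left = d.cdf(np.nextafter(pts, -np.inf))
        stat = max(
            np.max(np.abs(ecdf_right - cdf_right)),
            np.max(np.abs(ecdf_left - cdf_left)),
        )
    stat = float(stat)
    return GofResult(test="ks", statistic=stat, z_score=stat, n=n)


def ad_discrepancy(sample, ref: NoiseSpec) -> GofResult:
    """Anderson-Darling statistic of the CDF-transformed sample.

    ``A^2 = -n - (1/n) * sum_i (2i-1) [ln u_(i) + ln(1 - u_(n+1-i))]`` with
    ``u_(i)`` the sorted reference-CDF values of the sample.  Values of u at
    exactly 0 or 1 are clipped to ``[1e-12, 1 - 1e-12]`` so samples touching
    the support boundary keep a finite statistic.  The z-score is ``A^2/n``.
    """
    arr = np.sort(_check_sample(sample))
    n = arr.size
    u = np.asarray(ref.dist().cdf(arr), dtype=float)
    if np.all((u <= 0.0) | (u >= 1.0)):
        raise FloatingPointError(
            "all CDF-transformed values degenerate to 0 or 1"
        )
    u = np.clip(u, _AD_CLIP, 1.0 - _AD_CLIP)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1])))
    a2 = float(a2)
    return GofResult(test="anderson_darling", statistic=a2, z_score=a2 / n, n=n)


def _discrete_edges(ref: NoiseSpec) -> np.ndarray:
    # half-integer cuts covering essentially all reference mass; open tails
    d = ref.dist()
    lo = int(d.ppf(1e-12))
    hi = int(d.ppf(1 - 1e-12))
    inner = np.arange(lo, hi + 1) + 0.5
    return np.concatenate(([-np.inf], inner - 1.0, [inner[-1]], [np.inf]))


def _continuous_edges(ref: NoiseSpec, n: int, n_bins: Optional[int]) -> np.ndarray:
    b = n_bins if n_bins is not None else max(2, math.ceil(2 * n ** 0.4))
    q = np.linspace(0.0, 1.0, b + 1)
    edges = ref.dist().ppf(q)
    edges[0], edges[-1] = -np.inf, np.inf
    return np.unique(edges)


def _merge_tails(counts: np.ndarray, expected: np.ndarray, min_expected: float):
    """Greedily merge tail bins until every expected count reaches the floor."""
    c = list(counts)
    e = list(expected)
    while len(e) > 2 and e[0] < min_expected:
        c[0] = c.pop(0) + c[0]
        e[0] = e.pop(0) + e[0]
    while len(e) > 2 and e[-1] < min_expected:
        c[-1] = c.pop() + c[-1]
        e[-1] = e.pop() + e[-1]
    return np.array(c, dtype=float), np.array(e, dtype=float)


def chi2_discrepancy(sample, ref: NoiseSpec, n_bins: Optional[int] = None) -> GofResult:
    """Pearson chi-squared discrepancy on reference-probability bins.

    Continuous references use ``max(2, ceil(2 n^{2/5}))`` equiprobable bins
    (capped so each expects at least 5 counts); the discrete Poisson
    reference is binned on its integer support.  Tail bins are merged until
    every expected count is >= 5.  ``df = #bins - 1`` because the reference
    is fully specified.  The z-score is ``chi2 / n``.
    """
    arr = _check_sample(sample)
    n = arr.size
    if ref.discrete:
        edges = _discrete_edges(ref)
    else:
        if n_bins is None and n // 5 < max(2, math.ceil(2 * n ** 0.4)):
            n_bins = max(2, n // 5)
        edges = _continuous_edges(ref, n, n_bins)
    probs = np.diff(ref.dist().cdf(edges))
    expected = n * probs
    counts, _ = np.histogram(arr, bins=edges)
    counts, expected = _merge_tails(counts, expected, min_expected=5.0)
    if len(expected) < 2 or np.any(expected < 5.0):
        raise BinningError(
            "cannot form >= 2 bins with expected count >= 5; need a larger sample"
        )
    stat = float(np.sum((counts - expected) ** 2 / expected))
    df = len(expected) - 1
    return GofResult(
        test="chi_squared", statistic=stat, z_score=stat / n, n=n, df=df
    )


def _pvalue(result: GofResult) -> float:
    if result.test == "ks":
        return float(stats.kstwo.sf(result.statistic, result.n))
    if result.test == "chi_squared":
        return float(stats.chi2.sf(result.statistic, result.df))
    # Stephens' case-0 approximation for a fully specified reference
    z = result.statistic
    if z < 0.2:
        p = 1 - math.exp(-13.436 + 101.14 * z - 223.73 * z * z)
    elif z < 0.34:
        p = 1 - math.exp(-8.318 + 42.796 * z - 59.938 * z * z)
    elif z < 0.6:
        p = math.exp(0.9177 - 4.279 * z - 1.38 * z * z)
    elif z < 32:
        p = math.exp(1.2937 - 5.709 * z + 0.0186 * z * z)
    else:
        # outside the approximation's range; the null is hopeless anyway
        p = 0.0
    return min(max(p, 0.0), 1.0)


_DISPATCH = {
    "ks": ks_discrepancy,
    "anderson_darling": ad_discrepancy,
    "chi_squared": chi2_discrepancy,
}

# short aliases accepted at the API/CLI boundary
ALIASES = {"ad": "anderson_darling", "chi2": "chi_squared", "chi_square": "chi_squared"}


def gof_result(sample, ref: NoiseSpec, test: str,
               zscore_mode: str = "statistic", **kwargs) -> GofResult:
    """Run one named test and return its full :class:`GofResult`."""
    name = ALIASES.get(test, test)
    if name not in _DISPATCH:
        raise ValueError(f"unknown GoF test {test!r}; choose from {TESTS}")
    res = _DISPATCH[name](sample, ref, **kwargs)
    if zscore_mode == "statistic":
        return res
    if zscore_mode == "pvalue":
        p = _pvalue(res)
        z = max(0.0, float(special.ndtri(1 - min(max(p, 1e-300), 1 - 1e-16))))
        return GofResult(res.test, res.statistic, z, res.n, res.df)
    raise ValueError(f"unknown zscore_mode {zscore_mode!r}")


def gof_zscore(sample, ref: NoiseSpec, test: str,
               zscore_mode: str = "statistic", **kwargs) -> float:
    """The z-score of the named test (dispatch convenience)."""
    return gof_result(sample, ref, test, zscore_mode=zscore_mode, **kwargs).z_score
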