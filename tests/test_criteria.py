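import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gofselect import (
    DegenerateFitError,
    NoiseSpec,
    classic_criterion,
    criteria_table,
    entropy_criterion,
    gaussian_loglik_criterion,
    gf_criterion,
    noise_sample,
    residual_entropy,
    summarize_residuals,
)
from gofselect.criteria import CRITERIA, ResidualSummary


def make_summary(n=100, mse=1.0, variance=1.0, entropy=1.0, z=None, mean=0.0):
    return ResidualSummary(n=n, mean=mean, mse=mse, variance=variance,
                           entropy=entropy, z_score=z)


# ---------------------------------------------------------------------------
# residual entropy

def test_entropy_single_bin_floors_at_one_over_n():
    r = np.full(50, 3.14)
    assert residual_entropy(r) == pytest.approx(1 / 50)


def test_entropy_equal_two_bin_split():
    r = np.array([0.0, 0.1, 0.9, 1.0])
    assert residual_entropy(r, n_bins=2) == pytest.approx(math.log(2))


@pytest.mark.parametrize("b", [2, 4, 8])
def test_entropy_uniform_histogram_reaches_log_bins(b):
    # 3 points per bin, exactly uniform occupancy
    r = np.concatenate([np.full(3, i + 0.5) for i in range(b)])
    assert residual_entropy(r, bin_edges=np.arange(b + 1.0)) == pytest.approx(
        math.log(b))


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(-100, 100), min_size=2, max_size=50),
       st.integers(min_value=2, max_value=12))
def test_entropy_bounded_by_log_bin_count(values, b):
    h = residual_entropy(np.array(values), n_bins=b)
    assert h <= math.log(b) + 1e-12 or h == pytest.approx(1 / len(values))


def test_entropy_rejects_bad_edges():
    with pytest.raises(ValueError):
        residual_entropy([1.0, 2.0], bin_edges=[0.0, 0.0, 1.0])
    with pytest.raises(ValueError):
        residual_entropy([1.0, 5.0], bin_edges=[0.0, 2.0])  # does not cover
    with pytest.raises(ValueError):
        residual_entropy([np.nan, 1.0])


# ---------------------------------------------------------------------------
# the six criteria

def test_classic_aic_with_unit_mse_reduces_to_penalty():
    assert classic_criterion("aic", make_summary(n=100, mse=1.0), k=3) == 6.0


def test_classic_bic_with_unit_variance_reduces_to_penalty():
    value = classic_criterion("bic", make_summary(n=50, variance=1.0), k=2)
    assert value == pytest.approx(2 * math.log(50))


def test_classic_aic_log_mse_scaling():
    value = classic_criterion("aic", make_summary(n=10, mse=math.e ** 2), k=0)
    assert value == pytest.approx(20.0)


def test_entropy_criterion_equals_classic_when_h_is_one():
    s = make_summary(n=77, mse=2.3, variance=1.9, entropy=1.0)
    for kind in ("aic", "bic"):
        assert entropy_criterion(kind, s, 4) == pytest.approx(
            classic_criterion(kind, s, 4))


def test_entropy_criterion_divides_by_h():
    s = make_summary(n=10, mse=1.0, entropy=math.exp(-1))
    assert entropy_criterion("aic", s, 1) == pytest.approx(12.0)


def test_doubling_entropy_lowers_criterion_by_n_log2():
    s1 = make_summary(n=40, mse=5.0, variance=5.0, entropy=0.7)
    s2 = make_summary(n=40, mse=5.0, variance=5.0, entropy=1.4)
    for kind in ("aic", "bic"):
        assert entropy_criterion(kind, s1, 2) - entropy_criterion(kind, s2, 2) \
            == pytest.approx(40 * math.log(2))


def test_gf_criterion_z_zero_recovers_entropy_version():
    s = make_summary(n=60, mse=3.0, variance=2.5, entropy=0.8, z=0.0)
    for kind in ("aic", "bic"):
        assert gf_criterion(kind, s, 2) == pytest.approx(
            entropy_criterion(kind, s, 2))


def test_gf_criterion_unit_z_adds_n_log2():
    s = make_summary(n=60, mse=3.0, variance=2.5, entropy=0.8, z=1.0)
    assert gf_criterion("aic", s, 2) - entropy_criterion("aic", s, 2) \
        == pytest.approx(60 * math.log(2))


def test_gf_criterion_z_three_adds_n_log10():
    s = make_summary(n=100, mse=3.0, entropy=0.8, z=3.0)
    assert gf_criterion("aic", s, 2) - entropy_criterion("aic", s, 2) \
        == pytest.approx(100 * math.log(10))


def test_gf_requires_z_score():
    with pytest.raises(ValueError):
        gf_criterion("aic", make_summary(z=None), 1)


def test_degenerate_spread_rejected():
    with pytest.raises(DegenerateFitError):
        classic_criterion("aic", make_summary(mse=0.0), 1)
    with pytest.raises(DegenerateFitError):
        gaussian_loglik_criterion("bic", np.zeros(10), 1)


# ---------------------------------------------------------------------------
# Gaussian likelihood oracle

def test_loglik_closed_form():
    r = np.array([1.0, -1.0] * 5)  # mse exactly 1, n = 10
    assert gaussian_loglik_criterion("aic", r, 0) == pytest.approx(
        10 * (math.log(2 * math.pi) + 1))


def test_loglik_exceeds_classic_by_additive_constant(rng):
    for _ in range(20):
        r = rng.normal(0, rng.uniform(0.5, 4), 150)
        s = summarize_residuals(r)
        for kind in ("aic", "bic"):
            gap = gaussian_loglik_criterion(kind, r, 3) - classic_criterion(
                kind, ResidualSummary(s.n, s.mean, s.mse, s.mse, s.entropy), 3)
            assert gap == pytest.approx(150 * (math.log(2 * math.pi) + 1),
                                        abs=1e-9)


def test_loglik_scaling_shift():
    r = np.array([0.5, -1.5, 2.0, -1.0, 0.7])
    c = 3.0
    gap = gaussian_loglik_criterion("aic", c * r, 2) - \
        gaussian_loglik_criterion("aic", r, 2)
    assert gap == pytest.approx(len(r) * math.log(c ** 2))


# ---------------------------------------------------------------------------
# summary invariants

def test_mse_decomposes_into_variance_plus_squared_mean(rng):
    r = rng.gamma(3, 2, 500)
    s = summarize_residuals(r)
    assert s.mse == pytest.approx(s.variance + s.mean ** 2, abs=1e-9)


@settings(derandomize=True, max_examples=50)
@given(st.integers(min_value=0, max_value=20))
def test_penalty_strictly_increasing_in_k(k):
    s = make_summary(n=30, mse=2.0, variance=1.5, entropy=0.9, z=0.3)
    for fn in (classic_criterion, entropy_criterion, gf_criterion):
        for kind in ("aic", "bic"):
            assert fn(kind, s, k + 1) > fn(kind, s, k)


def test_constant_shift_moves_aic_not_bic(rng):
    r = rng.normal(0, 2, 300)
    shifted = r + 5.0
    s0, s1 = summarize_residuals(r), summarize_residuals(shifted)
    assert classic_criterion("bic", s0, 2) == pytest.approx(
        classic_criterion("bic", s1, 2), abs=1e-9)
    assert classic_criterion("aic", s1, 2) > classic_criterion("aic", s0, 2)


# ---------------------------------------------------------------------------
# criteria_table

def test_table_contains_all_six_and_is_deterministic(rng):
    ref = NoiseSpec.gaussian(0, 3)
    r = rng.normal(0, 3, 400)
    t1 = criteria_table(r, k=3, ref=ref, test="ks")
    t2 = criteria_table(r, k=3, ref=ref, test="ks")
    assert set(t1.values) == set(CRITERIA)
    assert t1.values == t2.values
    frame = t1.to_frame()
    assert len(frame) == 6
    assert frame["z_score"].nunique() == 1


def test_table_penalty_difference_between_k3_and_k5(rng):
    ref = NoiseSpec.gaussian(0, 3)
    r = rng.normal(0, 3, 200)
    t3 = criteria_table(r, k=3, ref=ref)
    t5 = criteria_table(r, k=5, ref=ref)
    for crit in CRITERIA:
        expected = 4.0 if crit.startswith("aic") else 2 * math.log(200)
        assert t5.values[crit] - t3.values[crit] == pytest.approx(expected)


def test_gf_close_to_entropy_version_under_null(rng):
    ref = NoiseSpec.gaussian(0, 3)
    r = noise_sample(ref, 2000, seed=1)
    t = criteria_table(r, k=2, ref=ref, test="ks")
    z = t.summary.z_score
    bound = 2000 * math.log(1 + z ** 2) + 1e-9
    assert abs(t.values["aic_gf"] - t.values["aic_h"]) <= bound


def test_gf_converges_to_entropy_version_with_n():
    """|AIC_GF - AIC_H| = n ln(1+Z^2) shrinks as the sample grows when the
    model is correct (Anderson-Darling z, whose statistic is O(1) under the
    null so the gap is O(A^4/n))."""
    ref = NoiseSpec.gamma(3, 2)
    gaps = []
    for n in (100, 1000, 10_000):
        g = [abs(criteria_table(noise_sample(ref, n, seed=s), k=1, ref=ref,
                                test="anderson_darling").values["aic_gf"]
                 - criteria_table(noise_sample(ref, n, seed=s), k=1, ref=ref,
                                  test="anderson_darling").values["aic_h"])
             for s in range(10)]
        gaps.append(np.mean(g))
    assert gaps[0] > gaps[1] > gaps[2]
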