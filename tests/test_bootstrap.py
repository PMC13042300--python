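"""Bootstrapped effect of food deprivation: oracle checks and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foragestat import (
    BootstrapConfig,
    bootstrap_difference,
    enumerate_bootstrap_oracle,
    percentile_ci,
    resample_with_replacement,
)

lattice = st.lists(
    st.sampled_from([0.0, 10.0, 20.0, 30.0, 50.0, 70.0, 90.0, 100.0]),
    min_size=2,
    max_size=6,
)


def test_resample_single_element_source():
    rng = np.random.default_rng(0)
    assert list(resample_with_replacement([42.0], 3, rng)) == [42.0, 42.0, 42.0]


def test_resample_deterministic_under_seed():
    a = resample_with_replacement([5, 6, 4], 3, np.random.default_rng(7))
    b = resample_with_replacement([5, 6, 4], 3, np.random.default_rng(7))
    assert np.array_equal(a, b)


def test_resample_uniform_frequency():
    rng = np.random.default_rng(1)
    draws = resample_with_replacement([0.0, 100.0], 10_000, rng)
    freq = np.mean(draws == 0.0)
    se = np.sqrt(0.25 / 10_000)
    assert abs(freq - 0.5) <= 3 * se


def test_resample_empty_rejected():
    with pytest.raises(ValueError):
        resample_with_replacement([], 3, np.random.default_rng(0))


@pytest.mark.parametrize(
    "values,alpha,expected",
    [
        (np.arange(1, 1001), 0.05, (26.0, 975.0)),
        (np.arange(1, 41), 0.05, (2.0, 39.0)),
        (np.full(100, 3.5), 0.05, (3.5, 3.5)),
    ],
)
def test_percentile_ci_trimming_rule(values, alpha, expected):
    assert percentile_ci(values, alpha) == expected


def test_percentile_ci_rejects_empty_and_overtrim():
    with pytest.raises(ValueError):
        percentile_ci([], alpha=0.05)
    with pytest.raises(ValueError):
        percentile_ci([1.0, 2.0], alpha=1.9)  # trimming would drop everything


def test_constant_samples_collapse_to_zero():
    res = bootstrap_difference(
        [50.0, 50.0, 50.0], [50.0, 50.0, 50.0], BootstrapConfig(n_reps=500, seed=0)
    )
    assert res.mean_of_means == 0.0
    assert res.mean_of_sds == 0.0
    assert (res.ci_low, res.ci_high) == (0.0, 0.0)


def test_enumeration_oracle_worked_example():
    # fed=[0,100], fd=[100,100]: fed resamples (0,0),(0,100),(100,0),(100,100)
    # give difference SDs 0, 70.71, 70.71, 0 and means 100, 50, 50, 0.
    mean, sd = enumerate_bootstrap_oracle([0.0, 100.0], [100.0, 100.0])
    assert mean == pytest.approx(50.0)
    assert sd == pytest.approx((0 + 2 * 100 / np.sqrt(2)) / 4)


def test_enumeration_oracle_degenerate_single_pair():
    mean, sd = enumerate_bootstrap_oracle([3.0], [10.0])
    assert (mean, sd) == (7.0, 0.0)


def test_enumeration_oracle_guards_blowup():
    with pytest.raises(ValueError, match="enumeration"):
        enumerate_bootstrap_oracle(np.arange(30.0), np.arange(30.0))


def test_bootstrap_matches_oracle_within_mc_error():
    fed, fd = [0.0, 100.0], [100.0, 100.0]
    res = bootstrap_difference(fed, fd, BootstrapConfig(n_reps=50_000, seed=11))
    exact_mean, exact_sd = enumerate_bootstrap_oracle(fed, fd)
    se_mean = res.replicate_means.std(ddof=1) / np.sqrt(res.n_reps)
    se_sd = res.replicate_sds.std(ddof=1) / np.sqrt(res.n_reps)
    assert abs(res.mean_of_means - exact_mean) <= 4 * se_mean
    assert abs(res.mean_of_sds - exact_sd) <= 4 * se_sd


@settings(deadline=None, derandomize=True, max_examples=25)
@given(lattice, lattice)
def test_expectation_identity(fed, fd):
    """E[replicate mean] equals the plain difference of sample means."""
    res = bootstrap_difference(fed, fd, BootstrapConfig(n_reps=4000, seed=5))
    expected = np.mean(fd) - np.mean(fed)
    se = res.replicate_means.std(ddof=1) / np.sqrt(res.n_reps)
    assert abs(res.mean_of_means - expected) <= max(4 * se, 1e-12)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(lattice, lattice)
def test_sd_triangle_bound(fed, fd):
    res = bootstrap_difference(fed, fd, BootstrapConfig(n_reps=2000, seed=5))
    bound = np.std(fed, ddof=1) + np.std(fd, ddof=1) + 1e-9
    assert res.mean_of_sds <= bound
    if np.ptp(fed) == 0 and np.ptp(fd) == 0:
        assert res.mean_of_sds == 0.0


def test_antisymmetry_exact_under_oracle():
    fed, fd = [10.0, 40.0, 70.0], [0.0, 90.0]
    m1, _ = enumerate_bootstrap_oracle(fed, fd)
    m2, _ = enumerate_bootstrap_oracle(fd, fed)
    assert m1 == pytest.approx(-m2)


def test_location_equivariance_under_shared_seed():
    fed = [10.0, 30.0, 60.0]
    fd = [40.0, 70.0, 90.0]
    cfg = BootstrapConfig(n_reps=2000, seed=9)
    base = bootstrap_difference(fed, fd, cfg)
    shifted = bootstrap_difference(fed, [v + 7.0 for v in fd], cfg)
    assert shifted.mean_of_means == pytest.approx(base.mean_of_means + 7.0)
    assert shifted.ci_low == pytest.approx(base.ci_low + 7.0)
    assert shifted.ci_high == pytest.approx(base.ci_high + 7.0)


def test_determinism_bit_identical():
    cfg = BootstrapConfig(n_reps=1000, seed=123)
    a = bootstrap_difference([0, 50, 100], [50, 100], cfg)
    b = bootstrap_difference([0, 50, 100], [50, 100], cfg)
    assert np.array_equal(a.replicate_means, b.replicate_means)
    assert a.to_dict() == b.to_dict()


def test_smaller_n_rule_and_pseudo_n():
    res = bootstrap_difference(
        np.zeros(7), np.ones(4), BootstrapConfig(n_reps=10, seed=0)
    )
    assert res.m_pairs == 4
    assert res.pseudo_n == 10  # 7 + 4 - 1


def test_m1_sd_reported_zero_with_warning():
    with pytest.warns(RuntimeWarning, match="m=1"):
        res = bootstrap_difference([5.0], [9.0], BootstrapConfig(n_reps=100, seed=0))
    assert res.mean_of_sds == 0.0
    assert res.mean_of_means == pytest.approx(4.0)


def test_ci_width_shrinks_with_group_size():
    """Average CI width at n=30 is below that at n=5, same effect and noise."""
    rng = np.random.default_rng(42)
    widths = {}
    for n in (5, 30):
        w = []
        for i in range(40):
            fed = rng.binomial(10, 0.3, size=n) * 10.0
            fd = rng.binomial(10, 0.6, size=n) * 10.0
            res = bootstrap_difference(fed, fd, BootstrapConfig(n_reps=1000, seed=i))
            w.append(res.ci_high - res.ci_low)
        widths[n] = np.mean(w)
    assert widths[30] < widths[5]
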