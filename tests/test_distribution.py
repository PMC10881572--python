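"""Distributional functions: closed forms, stable limits, series vs quadrature."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from ofhl import (
    Params,
    SeriesConfig,
    SeriesConvergenceError,
    cdf,
    conditional_moment,
    extreme_order_dist,
    hazard,
    incomplete_moment,
    mean_residual_life,
    mean_waiting_time,
    median,
    mgf,
    pdf,
    quantile,
    random_sample,
    raw_moment,
    sf,
)
from ofhl.distribution import _raw_moment_quad

positive_shapes = st.floats(0.2, 5.0)


def test_param_validation_rejects_nonpositive():
    for bad in [(-1, 1), (0, 1), (1, 0), (1, -2), (np.nan, 1), (1, np.inf)]:
        with pytest.raises(ValueError):
            Params(*bad)


def test_pdf_closed_form_at_log3():
    # at x = log 3, theta = 1 the odds ratio g equals exactly 1
    p = Params(1.0, 1.0)
    assert pdf(math.log(3), p) == pytest.approx(1.5 * math.exp(-1.0), rel=1e-12)
    assert cdf(math.log(3), p) == pytest.approx(math.exp(-1.0), rel=1e-12)
    assert sf(math.log(3), p) == pytest.approx(1.0 - math.exp(-1.0), rel=1e-12)
    assert hazard(math.log(3), p) == pytest.approx(
        1.5 * math.exp(-1.0) / (1.0 - math.exp(-1.0)), rel=1e-12
    )


def test_density_limits_and_conventions():
    p = Params(1.0, 1.0)
    assert pdf(1e-12, p) == 0.0  # g -> inf kills the exponential factor
    assert pdf(-1.0, p) == 0.0
    assert cdf(-1.0, p) == 0.0 and cdf(0.0, p) == 0.0
    assert sf(-1.0, p) == 1.0
    assert cdf(1e6, Params(0.5, 1.0)) == pytest.approx(1.0, abs=1e-12)


def test_hazard_underflow_warns_not_crashes():
    p = Params(1.0, 1.0)
    with pytest.warns(RuntimeWarning):
        h = hazard(1e6, p)
    assert h == np.inf


def test_density_normalizes_on_parameter_grid():
    for a in (0.25, 0.5, 1.0, 1.5, 3.0):
        for t in (0.5, 1.0, 2.0):
            p = Params(a, t)
            m = median(p)
            lo, _ = integrate.quad(lambda x: pdf(x, p), 0, m, limit=200)
            hi, _ = integrate.quad(lambda x: pdf(x, p), m, np.inf, limit=200)
            assert lo + hi == pytest.approx(1.0, abs=1e-6), (a, t)


def test_quantile_closed_form_values():
    p = Params(1.0, 1.0)
    assert quantile(math.exp(-1.0), p) == pytest.approx(math.log(3.0), rel=1e-12)
    assert median(p) == pytest.approx(math.log(1.0 + 2.0 / math.log(2.0)), rel=1e-12)
    with pytest.raises(ValueError):
        quantile(0.0, p)
    with pytest.raises(ValueError):
        quantile(1.0, p)


def test_median_scale_property(params_grid):
    p = params_grid
    half = Params(p.alpha, 2.0 * p.theta)
    assert median(half) == pytest.approx(0.5 * median(p), rel=1e-14)
    assert median(p) == quantile(0.5, p)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(alpha=positive_shapes, theta=positive_shapes, u=st.floats(1e-6, 1 - 1e-6))
def test_cdf_quantile_round_trip(alpha, theta, u):
    p = Params(alpha, theta)
    assert cdf(quantile(u, p), p) == pytest.approx(u, abs=1e-10)


def test_random_sample_is_seed_deterministic():
    p = Params(1.5, 0.5)
    a = random_sample(100, p, 42)
    b = random_sample(100, p, 42)
    c = random_sample(100, p, 43)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)
    assert np.all(a > 0)
    with pytest.raises(ValueError):
        random_sample(0, p, 1)


def test_random_sample_passes_ks_against_cdf():
    p = Params(1.5, 0.5)
    x = random_sample(50_000, p, 7)
    d = stats.kstest(x, lambda z: cdf(z, p)).statistic
    assert d < 1.63 / math.sqrt(50_000)  # 1% asymptotic critical value


def test_sample_mean_matches_first_moment():
    p = Params(2.0, 1.0)
    x = random_sample(100_000, p, 11)
    mean = raw_moment(1, p)
    var = raw_moment(2, p) - mean**2
    se = math.sqrt(var / x.size)
    assert abs(x.mean() - mean) < 3 * se


class TestMoments:
    def test_series_agrees_with_quadrature_where_convergent(self):
        p = Params(0.25, 0.75)
        s = raw_moment(1, p, method="series")
        q = _raw_moment_quad(1, p)
        assert s == pytest.approx(q, rel=1e-4)

    def test_series_raises_in_asymptotic_regime_with_partial(self):
        # the termwise-integrated expansion is divergent for alpha(k+1) > r
        with pytest.raises(SeriesConvergenceError) as err:
            raw_moment(1, Params(2.0, 1.0), method="series")
        assert err.value.partial is not None

    def test_auto_agrees_with_quadrature_on_grid(self, params_grid):
        p = params_grid
        for r in (1, 2):
            assert raw_moment(r, p) == pytest.approx(
                _raw_moment_quad(r, p), rel=1e-4
            )

    def test_mean_scales_inversely_with_theta(self):
        m1 = raw_moment(1, Params(1.5, 0.5))
        m2 = raw_moment(1, Params(1.5, 1.0))
        assert m1 == pytest.approx(2.0 * m2, rel=1e-8)

    def test_variance_nonnegative(self, params_grid):
        p = params_grid
        assert raw_moment(2, p) >= raw_moment(1, p) ** 2

    def test_moment_order_validation(self):
        with pytest.raises(ValueError):
            raw_moment(0, Params(1, 1))

    def test_series_config_validation(self):
        with pytest.raises(ValueError):
            SeriesConfig(k_max=0)
        with pytest.raises(ValueError):
            SeriesConfig(rel_tol=2.0)


class TestMgf:
    def test_at_zero_is_one(self):
        assert mgf(0.0, Params(2.0, 2.0)) == 1.0

    def test_derivative_at_zero_is_mean(self):
        p = Params(2.0, 2.0)
        h = 1e-5
        fd = (mgf(h, p) - mgf(-h, p)) / (2 * h)
        assert fd == pytest.approx(raw_moment(1, p), rel=1e-4)

    def test_matches_quadrature(self):
        p = Params(2.0, 2.0)
        direct, _ = integrate.quad(lambda x: math.exp(0.1 * x) * pdf(x, p), 0, np.inf, limit=200)
        assert mgf(0.1, p) == pytest.approx(direct, rel=1e-3)

    def test_domain_guard(self):
        with pytest.raises(ValueError):
            mgf(0.5, Params(0.5, 1.0))  # t >= theta*min(alpha,1) = 0.5


class TestTruncatedMoments:
    def test_incomplete_moment_limits(self):
        p = Params(1.25, 1.75)
        assert incomplete_moment(1, 1e6, p) == pytest.approx(raw_moment(1, p), rel=1e-4)
        assert incomplete_moment(1, 1e-9, p) == pytest.approx(0.0, abs=1e-12)

    def test_incomplete_moment_matches_quadrature_at_median(self):
        p = Params(1.25, 1.75)
        y = median(p)
        direct, _ = integrate.quad(lambda x: x * pdf(x, p), 0, y, limit=200)
        assert incomplete_moment(1, y, p) == pytest.approx(direct, rel=1e-4)

    def test_law_of_total_expectation(self, rng):
        for _ in range(5):
            p = Params(rng.uniform(0.5, 2.5), rng.uniform(0.5, 2.5))
            y = float(quantile(rng.uniform(0.2, 0.8), p))
            total = conditional_moment(1, y, p) * sf(y, p) + incomplete_moment(1, y, p)
            assert total == pytest.approx(raw_moment(1, p), abs=1e-8)

    def test_conditional_moment_matches_tail_quadrature(self):
        p = Params(1.5, 0.5)
        tail, _ = integrate.quad(lambda x: x * pdf(x, p), 1.0, np.inf, limit=200)
        assert conditional_moment(1, 1.0, p) == pytest.approx(tail / sf(1.0, p), rel=1e-4)

    def test_mean_residual_life_identities(self):
        p = Params(1.25, 1.25)
        assert mean_residual_life(1e-9, p) == pytest.approx(raw_moment(1, p), rel=1e-4)
        t = 2.0
        assert mean_residual_life(t, p) == pytest.approx(
            conditional_moment(1, t, p) - t, abs=1e-8
        )
        expect, _ = integrate.quad(lambda x: (x - t) * pdf(x, p), t, np.inf, limit=200)
        assert mean_residual_life(t, p) == pytest.approx(expect / sf(t, p), rel=1e-4)
        assert mean_residual_life(t, p) >= 0.0

    def test_mean_waiting_time(self):
        p = Params(1.5, 0.5)
        t = 2.0
        direct, _ = integrate.quad(lambda x: x * pdf(x, p), 0, t, limit=200)
        expected = t - direct / cdf(t, p)
        got = mean_waiting_time(t, p)
        assert got == pytest.approx(expected, rel=1e-4)
        assert 0.0 <= got <= t
        # rearrangement: pi_bar(t) + phi_1(t)/F(t) = t
        assert got + incomplete_moment(1, t, p) / cdf(t, p) == pytest.approx(t, abs=1e-8)


class TestOrderStatistics:
    def test_n1_reduces_to_parent(self):
        p = Params(1.3, 0.8)
        for extreme in ("minimum", "maximum"):
            d, c = extreme_order_dist(2.0, p, 1, extreme)
            assert d == pytest.approx(pdf(2.0, p), rel=1e-14)
            assert c == pytest.approx(cdf(2.0, p), rel=1e-14)

    def test_maximum_cdf_at_median(self):
        p = Params(1.0, 1.0)
        _, c = extreme_order_dist(median(p), p, 3, "maximum")
        assert c == pytest.approx(0.125, rel=1e-10)

    def test_extreme_densities_normalize(self):
        p = Params(1.0, 1.0)
        for extreme in ("minimum", "maximum"):
            val, _ = integrate.quad(
                lambda x: extreme_order_dist(x, p, 5, extreme)[0], 0, np.inf, limit=200
            )
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            extreme_order_dist(1.0, Params(1, 1), 0, "maximum")
        with pytest.raises(ValueError):
            extreme_order_dist(1.0, Params(1, 1), 3, "middle")


def test_hazard_matches_definition_on_grid():
    p = Params(0.7, 1.2)
    x = np.linspace(0.1, 10.0, 100)
    np.testing.assert_allclose(hazard(x, p), pdf(x, p) / sf(x, p), atol=1e-12)
    assert np.all(hazard(x, p) > 0)
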