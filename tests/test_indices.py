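"""Unit tests for heat degree days, PET and SPEI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cropcsi as cc
from cropcsi.errors import ConfigurationError, DataError, InsufficientDataError
from cropcsi.indices import (
    SpeiTransform,
    fit_loglogistic_pwm,
    fit_spei_transform,
    thornthwaite_pet,
)


class TestHdd:
    def test_toy_summer(self):
        assert cc.compute_hdd_cell([31.0, 29.0, 33.0], t_thr=30.0) == 4.0

    def test_all_below_threshold_is_zero(self):
        assert cc.compute_hdd_cell(np.full(92, 25.0)) == 0.0

    def test_default_threshold_is_30(self):
        # conservative threshold near the optimum for maize growth processes
        assert cc.compute_hdd_cell([31.0]) == 1.0

    def test_missing_days_beyond_tolerance(self):
        x = np.full(92, 31.0)
        x[:10] = np.nan
        with pytest.raises(DataError):
            cc.compute_hdd_cell(x)

    def test_grid_matches_per_cell_brute_force(self, rng):
        tmax = 20 + 12 * rng.standard_normal((3, 365, 2, 2))
        grid = cc.hdd_jja(tmax, t_thr=30.0)
        for y in range(3):
            for i in range(2):
                for j in range(2):
                    brute = sum(max(t - 30.0, 0.0)
                                for t in tmax[y, 151:243, i, j])
                    assert grid[y, i, j] == pytest.approx(brute, abs=1e-10)

    @given(st.lists(st.floats(-10, 45), min_size=5, max_size=92),
           st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_translation_covariant(self, days, delta):
        base = cc.compute_hdd_cell(days)
        shifted = cc.compute_hdd_cell(np.asarray(days) + delta)
        assert shifted >= base
        hot = np.asarray(days) + 50.0  # all above threshold
        assert (cc.compute_hdd_cell(hot + delta)
                == pytest.approx(cc.compute_hdd_cell(hot) + len(days) * delta))


class TestThornthwaite:
    def test_cold_month_has_zero_pet(self):
        t = np.array([-5.0, 1, 5, 9, 14, 18, 20, 19, 15, 10, 4, -1])
        pet = thornthwaite_pet(t, 45.0)
        assert pet[0] == 0.0 and pet[11] == 0.0
        assert np.all(pet >= 0)

    def test_equator_uniform_temperature_symmetry(self):
        # at the equator the daylight correction is identical for all months,
        # so equal-length months with equal temperature evaporate equally
        pet = thornthwaite_pet(np.full(12, 20.0), 0.0)
        months_31 = [0, 2, 4, 6, 7, 9, 11]
        assert np.ptp(pet[months_31]) < 1e-6

    def test_latitude_domain_error(self):
        with pytest.raises(ConfigurationError):
            thornthwaite_pet(np.full(12, 10.0), 95.0)

    def test_against_independent_formula(self):
        # scalar re-implementation of the published formula as oracle
        t = np.array([1.0, 2, 6, 10, 15, 19, 21, 20, 16, 11, 5, 2])
        lat = 45.0
        pet = thornthwaite_pet(t, lat)
        i_idx = sum((max(tm, 0.0) / 5.0) ** 1.514 for tm in t)
        a = 6.75e-7 * i_idx**3 - 7.71e-5 * i_idx**2 + 1.792e-2 * i_idx + 0.49239
        ndays = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
        mid = np.cumsum([0] + ndays[:-1]) + np.array(ndays) // 2 + 1
        for m in range(12):
            decl = 0.4093 * np.sin(2 * np.pi * mid[m] / 365.0 - 1.405)
            omega = np.arccos(np.clip(-np.tan(np.deg2rad(lat)) * np.tan(decl), -1, 1))
            day_len = 24 / np.pi * omega
            expected = (16.0 * (10.0 * max(t[m], 0.0) / i_idx) ** a
                        * (day_len / 12.0) * (ndays[m] / 30.0))
            assert pet[m] == pytest.approx(expected, rel=1e-10)

    def test_hargreaves_nonnegative_and_summer_peaked(self):
        t = np.array([1.0, 2, 6, 10, 15, 19, 21, 20, 16, 11, 5, 2])
        pet = cc.hargreaves_pet(t, t + 6.0, 45.0)
        assert np.all(pet >= 0)
        assert pet[6] > pet[0]


class TestSpei:
    def test_median_maps_to_zero(self):
        tr = SpeiTransform(params=(10.0, 3.0, -5.0), reference=np.zeros(30))
        median = -5.0 + 10.0  # F = 1/2 at x - gamma = alpha
        assert tr(np.array([median]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_water_balance(self, rng):
        d = rng.normal(0, 20, size=40)
        tr = fit_spei_transform(d)
        xs = np.linspace(d.min(), d.max(), 50)
        assert np.all(np.diff(tr(xs)) > 0)

    def test_parametric_recovery(self, rng):
        # data from a known log-logistic on the water-balance scale (mm):
        # fitted quantiles match the generating ones within 2%
        alpha, beta, gamma_loc = 60.0, 8.0, -120.0
        sample = stats.fisk.rvs(beta, loc=gamma_loc, scale=alpha,
                                size=10_000, random_state=rng)
        params = fit_loglogistic_pwm(sample)
        assert params is not None
        a_fit, b_fit, g_fit = params
        for p in (0.1, 0.5, 0.9):
            q_true = stats.fisk.ppf(p, beta, loc=gamma_loc, scale=alpha)
            q_fit = g_fit + a_fit * (p / (1 - p)) ** (1 / b_fit)
            assert q_fit == pytest.approx(q_true, rel=0.02)

    def test_reference_period_too_short(self):
        with pytest.raises(InsufficientDataError):
            fit_spei_transform(np.arange(10.0))

    def test_empirical_fallback_is_standardised(self, rng):
        d = rng.normal(0, 15, size=30)
        tr = SpeiTransform(params=None, reference=np.sort(d))
        z = tr(d)
        assert abs(z.mean()) < 0.1
        assert abs(z.std(ddof=1) - 1.0) < 0.2

    def test_self_standardisation_per_cell(self, climate):
        pet = thornthwaite_pet(climate.tmean, climate.lat)
        spei, _ = cc.spei_grid(climate.precip, pet, 2, 7)
        assert np.all(np.abs(spei.mean(axis=0)) < 0.1)
        assert np.all(np.abs(spei.std(axis=0, ddof=1) - 1.0) < 0.15)

    def test_window_leaving_year_rejected(self, climate):
        pet = thornthwaite_pet(climate.tmean, climate.lat)
        with pytest.raises(ConfigurationError):
            cc.aggregate_water_balance(climate.precip, pet, 3, 2)


class TestAggregation:
    def test_uniform_field_returns_value(self, mask):
        field = np.full(mask.weights.shape, 3.7)
        assert cc.aggregate_to_country(field, mask, "C01") == pytest.approx(3.7)

    def test_two_cell_arithmetic(self):
        from cropcsi.synthetic import CropMask

        m = CropMask(countries=("A",), cell_country=np.zeros((1, 2), int),
                     weights=np.array([[0.5, 0.5]]), areas={"A": 1.0})
        assert cc.aggregate_to_country(np.array([[2.0, 4.0]]), m, "A") == 3.0

    def test_matches_brute_force_dot_product(self, mask, rng):
        field = rng.standard_normal((5,) + mask.weights.shape)
        for country in mask.countries:
            w = mask.country_weights(country)
            expected = (field * w).sum(axis=(-2, -1)) / w.sum()
            got = cc.aggregate_to_country(field, mask, country)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_commutes_with_linear_combinations(self, mask, rng):
        x = rng.standard_normal(mask.weights.shape)
        y = rng.standard_normal(mask.weights.shape)
        lhs = cc.aggregate_to_country(2.0 * x + 3.0 * y, mask, "C02")
        rhs = (2.0 * cc.aggregate_to_country(x, mask, "C02")
               + 3.0 * cc.aggregate_to_country(y, mask, "C02"))
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_zero_weight_country_rejected(self, mask):
        from cropcsi.synthetic import CropMask

        empty = CropMask(countries=("A", "B"),
                         cell_country=np.zeros((2, 2), int),
                         weights=np.full((2, 2), 0.25), areas={"A": 1, "B": 1})
        with pytest.raises(ConfigurationError):
            cc.aggregate_to_country(np.ones((2, 2)), empty, "B")
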