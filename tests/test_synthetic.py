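"""Tests of the synthetic climate/yield/forecast generator."""

import numpy as np
import pytest

import cropcsi as cc
from cropcsi.errors import ConfigurationError
from cropcsi.indices import JJA_START, JJA_STOP


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_cfg, climate, mask, yields_truth):
        clim2 = cc.generate_climate(small_cfg)
        np.testing.assert_array_equal(climate.tmax, clim2.tmax)
        np.testing.assert_array_equal(climate.precip, clim2.precip)
        mask2 = cc.generate_crop_mask(small_cfg)
        np.testing.assert_array_equal(mask.weights, mask2.weights)
        yields, _ = yields_truth
        yields2, _ = cc.generate_yields(clim2, mask2, small_cfg)
        np.testing.assert_array_equal(yields["yield"].to_numpy(),
                                      yields2["yield"].to_numpy())
        fc1 = cc.generate_forecasts(climate, small_cfg, 5)
        fc2 = cc.generate_forecasts(climate, small_cfg, 5)
        np.testing.assert_array_equal(fc1.tmax_jja, fc2.tmax_jja)

    def test_different_seed_differs(self, small_cfg, climate):
        import dataclasses

        cfg2 = dataclasses.replace(small_cfg, seed=small_cfg.seed + 1)
        clim2 = cc.generate_climate(cfg2)
        assert not np.array_equal(climate.tmax, clim2.tmax)


class TestClimate:
    def test_degenerate_variances_give_identical_years(self):
        cfg = cc.SyntheticConfig(seed=0, grid_shape=(3, 3), n_countries=1,
                                 t_anom_sd=0.0, p_anom_sd=0.0,
                                 daily_noise_sd=0.0, p_cell_noise_sd=0.0)
        clim = cc.generate_climate(cfg)
        hdd = cc.hdd_jja(clim.tmax)
        assert np.ptp(hdd, axis=0).max() == 0.0
        assert np.ptp(clim.tmean, axis=0).max() == 0.0

    def test_summer_tmax_straddles_threshold(self, climate, small_cfg):
        hdd = cc.hdd_jja(climate.tmax, small_cfg.t_thr)
        assert (hdd > 0).any() and (hdd == 0).any()

    def test_precip_nonnegative_everywhere(self, climate):
        assert climate.precip.min() >= 0.0

    def test_spatial_correlation_decays_with_distance(self):
        # interannual July tmax correlation: adjacent >> maximally separated
        cfg = cc.SyntheticConfig(seed=42, n_years=200, grid_shape=(6, 6),
                                 n_countries=1, spatial_corr_length=2.0)
        clim = cc.generate_climate(cfg)
        july = clim.tmax[:, 181:212].mean(axis=1)
        near = np.corrcoef(july[:, 0, 0], july[:, 0, 1])[0, 1]
        far = np.corrcoef(july[:, 0, 0], july[:, 5, 5])[0, 1]
        assert near > far

    def test_too_few_years_rejected(self):
        with pytest.raises(ConfigurationError):
            cc.SyntheticConfig(n_years=10)


class TestCropMask:
    def test_weights_normalised_per_country(self, mask):
        for c in mask.countries:
            assert mask.country_weights(c).sum() == pytest.approx(1.0, abs=1e-12)
        assert mask.weights.min() >= 0.0

    def test_countries_partition_grid(self, mask, small_cfg):
        counts = np.zeros(small_cfg.grid_shape, int)
        for c in mask.countries:
            counts += mask.country_cells(c)
        assert np.all(counts == 1)

    def test_uniform_single_country_weights(self):
        from cropcsi.synthetic import CropMask

        m = CropMask(countries=("A",), cell_country=np.zeros((2, 2), int),
                     weights=np.full((2, 2), 0.25), areas={"A": 1.0})
        assert np.all(m.country_weights("A") == 0.25)

    def test_more_countries_than_cells_rejected(self):
        with pytest.raises(ConfigurationError):
            cc.SyntheticConfig(grid_shape=(2, 2), n_countries=5)


class TestYields:
    def test_noise_free_limit_is_exact_linear_signal(self):
        cfg = cc.SyntheticConfig(seed=9, grid_shape=(3, 3), n_countries=1,
                                 noise_sd=0.0, trend_coeffs=(0.0, 0.0))
        clim = cc.generate_climate(cfg)
        msk = cc.generate_crop_mask(cfg)
        yields, truth = cc.generate_yields(clim, msk, cfg)
        t = truth["countries"]["C01"]
        y = np.log(yields["yield"].to_numpy())
        recon = np.log(cfg.base_yield) + cfg.signal_scale * t["signal"]
        np.testing.assert_allclose(y, recon, atol=1e-12)
        # a CSI fit on the standardised anomalies is then near-perfect
        y_std = cc.detrend_standardise(cfg.years, yields["yield"].to_numpy(),
                                       transform="log", standardise=True)
        res = cc.loo_q2(y_std, t["spei_star"], t["hdd_std_star"])
        assert res.q2 > 0.97

    def test_zero_climate_effect_gives_no_skill(self):
        # with gamma = 0 the LOO Q^2 of the indices is <= 0 in expectation
        import dataclasses

        base = cc.SyntheticConfig(seed=0, grid_shape=(3, 3), n_countries=1,
                                  yield_coeffs=(0.0, 0.0))
        clim = cc.generate_climate(base)
        msk = cc.generate_crop_mask(base)
        q2s = []
        for seed in range(100):
            cfg = dataclasses.replace(base, seed=seed)
            yields, truth = cc.generate_yields(clim, msk, cfg)
            t = truth["countries"]["C01"]
            y_std = cc.detrend_standardise(
                cfg.years, yields["yield"].to_numpy(),
                transform="log", standardise=True)
            q2s.append(cc.loo_q2(y_std, t["spei_star"], t["hdd_std_star"]).q2)
        assert np.mean(q2s) <= 0.0

    def test_ground_truth_signal_decomposition(self, small_cfg, yields_truth):
        yields, truth = yields_truth
        t = truth["countries"]["C01"]
        np.testing.assert_allclose(
            t["signal"],
            truth["gamma_spei"] * t["spei_star"] - truth["gamma_hdd"] * t["hdd_std_star"],
            atol=1e-12)


class TestForecasts:
    def test_perfect_skill_reproduces_observations(self, climate, small_cfg):
        fc = cc.generate_forecasts(climate, small_cfg, 5, skill_rho=1.0)
        for mem in range(small_cfg.n_members):
            np.testing.assert_allclose(fc.tmean[mem], climate.tmean[:, 4:8],
                                       atol=1e-12)
            np.testing.assert_allclose(
                fc.tmax_jja[mem], climate.tmax[:, JJA_START:JJA_STOP], atol=1e-12)

    def test_lead_window_covers_jja(self, climate, small_cfg):
        for start in (5, 6):
            fc = cc.generate_forecasts(climate, small_cfg, start)
            assert {6, 7, 8}.issubset(fc.months)
            assert len(fc.months) == 4

    def test_zero_skill_uncorrelated_with_truth(self):
        cfg = cc.SyntheticConfig(seed=3, n_years=200, grid_shape=(3, 3),
                                 n_countries=1)
        clim = cc.generate_climate(cfg)
        fc = cc.generate_forecasts(clim, cfg, 5, skill_rho=0.0)
        obs = clim.tmean[:, 6, 0, 0]
        ens = fc.tmean[:, :, 2, 0, 0].mean(axis=0)
        assert abs(np.corrcoef(obs, ens)[0, 1]) < 0.15

    def test_ensemble_mean_beats_single_member(self):
        cfg = cc.SyntheticConfig(seed=4, n_years=200, grid_shape=(3, 3),
                                 n_countries=1)
        clim = cc.generate_climate(cfg)
        fc = cc.generate_forecasts(clim, cfg, 5, skill_rho=0.8)
        obs = clim.tmean[:, 6, 0, 0]
        ens = fc.tmean[:, :, 2, 0, 0].mean(axis=0)
        single = fc.tmean[0, :, 2, 0, 0]
        assert (np.corrcoef(obs, ens)[0, 1] > np.corrcoef(obs, single)[0, 1])

    def test_skill_monotone_in_rho(self):
        cfg = cc.SyntheticConfig(seed=5, n_years=200, grid_shape=(3, 3),
                                 n_countries=1)
        clim = cc.generate_climate(cfg)
        obs = clim.tmean[:, 6, 1, 1]
        corrs = []
        for rho in (0.0, 0.4, 0.8, 1.0):
            fc = cc.generate_forecasts(clim, cfg, 5, skill_rho=rho, seed_tag=7)
            ens = fc.tmean[:, :, 2, 1, 1].mean(axis=0)
            corrs.append(np.corrcoef(obs, ens)[0, 1])
        assert np.all(np.diff(corrs) > 0)
        assert corrs[-1] == pytest.approx(1.0, abs=1e-12)

    def test_member_climatology_matches_observations(self):
        cfg = cc.SyntheticConfig(seed=6, n_years=200, grid_shape=(3, 3),
                                 n_countries=1)
        clim = cc.generate_climate(cfg)
        fc = cc.generate_forecasts(clim, cfg, 5, skill_rho=0.0)
        obs = clim.tmean[:, 5:8, 0, 0]
        mem = fc.tmean[:, :, 1:4, 0, 0]
        assert abs(mem.mean() - obs.mean()) < 0.15
        assert abs(mem.std() / obs.std() - 1.0) < 0.1

    def test_invalid_skill_rejected(self, climate, small_cfg):
        with pytest.raises(ConfigurationError):
            cc.generate_forecasts(climate, small_cfg, 5, skill_rho=1.5)
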