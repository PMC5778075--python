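"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pytest

import cropcsi as cc


@pytest.fixture(scope="session")
def small_cfg():
    return cc.SyntheticConfig(seed=1234, grid_shape=(4, 4), n_countries=2)


@pytest.fixture(scope="session")
def climate(small_cfg):
    return cc.generate_climate(small_cfg)


@pytest.fixture(scope="session")
def mask(small_cfg):
    return cc.generate_crop_mask(small_cfg)


@pytest.fixture(scope="session")
def yields_truth(small_cfg, climate, mask):
    return cc.generate_yields(climate, mask, small_cfg)


@pytest.fixture(scope="session")
def observed(small_cfg, climate, mask, yields_truth):
    yields, _ = yields_truth
    return cc.run_observed_analysis(climate, mask, yields)


@pytest.fixture(scope="session")
def strong_cfg():
    """Low-noise study where every country model should be significant."""
    return cc.SyntheticConfig(seed=77, grid_shape=(4, 4), n_countries=3,
                              noise_sd=0.3)


@pytest.fixture(scope="session")
def strong_study(strong_cfg):
    clim = cc.generate_climate(strong_cfg)
    msk = cc.generate_crop_mask(strong_cfg)
    yields, truth = cc.generate_yields(clim, msk, strong_cfg)
    obs = cc.run_observed_analysis(clim, msk, yields)
    return strong_cfg, clim, msk, yields, truth, obs


@pytest.fixture
def rng():
    return np.random.default_rng(0)
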