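"""Synthetic gridded climate, crop masks, yields and ensemble re-forecasts.

The generator emulates the statistical structure of the real study inputs:

* a harmonic seasonal cycle per variable with a weak north-south gradient,
  plus monthly, spatially correlated (exponential kernel) interannual anomaly
  fields shared between daily maximum and monthly mean temperature, plus
  small-scale noise (day-to-day for tmax, cell-level for precipitation);
* contiguous country blocks with random harvested-area weights normalised
  within each country, and a per-country total maize production area used as
  verification weight;
* national yields log(yield) = trend + s * (gamma_spei * SPEI* -
  gamma_hdd * HDD_std* + noise), where the two predictors are computed by the
  package's own index/de-trend pathway so the generating coefficients can be
  recovered downstream;
* ensemble re-forecasts built by mixing the observed anomaly (everything but
  the seasonal cycle) with independent member noise of identical law:
  dev_member = rho * dev_obs + sqrt(1 - rho^2) * dev_noise, then distorted by
  an additive bias and a multiplicative dispersion factor. rho = 1 with no
  distortion reproduces the observations exactly; rho = 0 gives a skill-free
  forecast with the observed climatology.

Daily maximum temperature is carried for June-August (the only days any
downstream consumer reads); monthly fields cover the full window.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SyntheticConfig
from .errors import ConfigurationError
from .indices import (
    JJA_START,
    JJA_STOP,
    MONTH_START_DOY,
    aggregate_to_country,
    hdd_jja,
    spei_grid,
    thornthwaite_pet,
)
from .detrend import fit_trend

JJA_MONTHS = (6, 7, 8)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ClimateGrid:
    """Observed synthetic climate: daily tmax plus monthly tmean/precip."""

    years: np.ndarray            # (Y,)
    lat: np.ndarray              # (nlat,)
    lon: np.ndarray              # (nlon,)
    tmax: np.ndarray             # (Y, 365, nlat, nlon), deg C
    tmean: np.ndarray            # (Y, 12, nlat, nlon), deg C
    precip: np.ndarray           # (Y, 12, nlat, nlon), mm/month
    tmax_clim: np.ndarray        # (365, nlat, nlon)
    tmean_clim: np.ndarray       # (12, nlat, nlon)
    precip_clim: np.ndarray      # (12, nlat, nlon)

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return len(self.lat), len(self.lon)


@dataclass
class EnsembleForecastGrid:
    """One re-forecast experiment: member fields over a 4-month lead window."""

    experiment: str
    start_month: int             # 5 (May) or 6 (June)
    months: Tuple[int, ...]      # the 4 lead months (calendar month numbers)
    years: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    tmax_jja: np.ndarray         # (M, Y, 92, nlat, nlon) June 1 - Aug 31 daily maxima
    tmean: np.ndarray            # (M, Y, 4, nlat, nlon)
    precip: np.ndarray           # (M, Y, 4, nlat, nlon)
    skill_rho: float

    @property
    def n_members(self) -> int:
        return self.tmax_jja.shape[0]

    def month_index(self, month: int) -> int:
        if month not in self.months:
            raise ConfigurationError(
                f"month {month} outside lead window {self.months}"
            )
        return self.months.index(month)


@dataclass
class CropMask:
    """Per-country harvested-area weights on the grid.

    ``cell_country`` assigns every cell to a country (index into
    ``countries``); weights are normalised to sum to one within each country.
    ``areas`` holds the total maize production area per country, used as the
    pooling weight in verification.
    """

    countries: Tuple[str, ...]
    cell_country: np.ndarray     # (nlat, nlon) int
    weights: np.ndarray          # (nlat, nlon) float, per-country normalised
    areas: Dict[str, float]

    def country_index(self, country: str) -> int:
        return self.countries.index(country)

    def country_cells(self, country: str) -> np.ndarray:
        return self.cell_country == self.country_index(country)

    def country_weights(self, country: str) -> np.ndarray:
        return np.where(self.country_cells(country), self.weights, 0.0)


# ---------------------------------------------------------------------------
# Climatology and anomaly machinery
# ---------------------------------------------------------------------------

def _lat_gradient(cfg: SyntheticConfig) -> np.ndarray:
    lat = cfg.lat0 + cfg.dlat * np.arange(cfg.grid_shape[0])
    return -0.25 * (lat - lat.mean())


def climatology_fields(cfg: SyntheticConfig) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seasonal-cycle fields (tmax 365-day, tmean/precip monthly)."""
    nlat, nlon = cfg.grid_shape
    grad = _lat_gradient(cfg)[:, None] * np.ones((1, nlon))
    doy = np.arange(1, 366)
    months = np.arange(1, 13)
    tmax_c = 16.0 + 12.0 * np.cos(2.0 * np.pi * (doy - 197) / 365.0)
    tmean_c = 9.0 + 10.0 * np.cos(2.0 * np.pi * (months - 7) / 12.0)
    precip_c = 70.0 - 15.0 * np.cos(2.0 * np.pi * (months - 7) / 12.0)
    tmax_clim = tmax_c[:, None, None] + grad[None, :, :]
    tmean_clim = tmean_c[:, None, None] + grad[None, :, :]
    precip_clim = np.broadcast_to(precip_c[:, None, None], (12, nlat, nlon)).copy()
    return tmax_clim, tmean_clim, precip_clim


@lru_cache(maxsize=8)
def _spatial_chol(shape: Tuple[int, int], length: float) -> np.ndarray:
    """Cholesky factor of the exponential spatial correlation over grid cells."""
    nlat, nlon = shape
    ii, jj = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    corr = np.exp(-d / max(length, 1e-9))
    return np.linalg.cholesky(corr + 1e-9 * np.eye(pts.shape[0]))


def _correlated_fields(rng: np.random.Generator, cfg: SyntheticConfig,
                       n: int) -> np.ndarray:
    """n spatially correlated unit-variance fields, shape (n, nlat, nlon)."""
    nlat, nlon = cfg.grid_shape
    chol = _spatial_chol(cfg.grid_shape, cfg.spatial_corr_length)
    z = rng.standard_normal((nlat * nlon, n))
    return (chol @ z).T.reshape(n, nlat, nlon)


def _draw_deviations(rng: np.random.Generator, cfg: SyntheticConfig,
                     months: Tuple[int, ...], n_years: int,
                     jja_days: bool = True
                     ) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Deviation-from-climatology fields with the generator's anomaly law.

    Returns (tmean_dev (Y, nm, nlat, nlon), precip_dev (Y, nm, nlat, nlon),
    tmax_dev (Y, 92, nlat, nlon) over June-August or None). Monthly anomaly
    fields are shared between tmean and daily tmax; precipitation receives an
    independent anomaly plus cell-level noise; tmax adds day-to-day noise.
    """
    nlat, nlon = cfg.grid_shape
    nm = len(months)
    anom_t = cfg.t_anom_sd * _correlated_fields(rng, cfg, n_years * nm).reshape(
        n_years, nm, nlat, nlon)
    anom_p = cfg.p_anom_sd * _correlated_fields(rng, cfg, n_years * nm).reshape(
        n_years, nm, nlat, nlon)
    precip_dev = anom_p + cfg.p_cell_noise_sd * rng.standard_normal(anom_p.shape)
    tmax_dev = None
    if jja_days:
        tmax_dev = np.zeros((n_years, JJA_STOP - JJA_START, nlat, nlon))
        for month in JJA_MONTHS:
            if month not in months:
                raise ConfigurationError("deviation window must include June-August")
            mi = months.index(month)
            d0 = int(MONTH_START_DOY[month - 1]) - JJA_START
            d1 = int(MONTH_START_DOY[month]) - JJA_START
            tmax_dev[:, d0:d1] = anom_t[:, mi, None, :, :]
        tmax_dev = tmax_dev + cfg.daily_noise_sd * rng.standard_normal(tmax_dev.shape)
    return anom_t, precip_dev, tmax_dev


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _rng(cfg: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, tag]))


def generate_climate(cfg: SyntheticConfig) -> ClimateGrid:
    """Observed synthetic climate with seasonal cycle + correlated anomalies.

    Summer daily maxima straddle the 30 degC HDD threshold: warm-anomaly years
    accumulate substantial exceedances while cool years may accumulate none.
    """
    if cfg.n_years < 2:
        raise ConfigurationError("need at least 2 years of climate")
    rng = _rng(cfg, 0)
    nlat, nlon = cfg.grid_shape
    n_years = cfg.n_years
    tmax_clim, tmean_clim, precip_clim = climatology_fields(cfg)

    months = tuple(range(1, 13))
    anom_t, precip_dev, _ = _draw_deviations(rng, cfg, months, n_years, jja_days=False)

    tmean = tmean_clim[None] + anom_t
    precip = np.clip(precip_clim[None] + precip_dev, 0.0, None)

    # daily tmax over the whole year: month anomaly + day-to-day noise
    month_of_day = np.searchsorted(MONTH_START_DOY[1:], np.arange(365), side="right")
    tmax = (tmax_clim[None]
            + anom_t[:, month_of_day]
            + cfg.daily_noise_sd * rng.standard_normal((n_years, 365, nlat, nlon)))

    lat = cfg.lat0 + cfg.dlat * np.arange(nlat)
    lon = cfg.lon0 + cfg.dlon * np.arange(nlon)
    return ClimateGrid(
        years=cfg.years, lat=lat, lon=lon,
        tmax=tmax, tmean=tmean, precip=precip,
        tmax_clim=tmax_clim, tmean_clim=tmean_clim, precip_clim=precip_clim,
    )


def generate_crop_mask(cfg: SyntheticConfig) -> CropMask:
    """Contiguous country blocks with random harvested-area weights."""
    rng = _rng(cfg, 1)
    nlat, nlon = cfg.grid_shape
    n_cells = nlat * nlon
    if cfg.n_countries > n_cells:
        raise ConfigurationError("more countries than grid cells")
    bounds = np.linspace(0, n_cells, cfg.n_countries + 1).round().astype(int)
    cell_country = np.empty(n_cells, dtype=int)
    for c in range(cfg.n_countries):
        cell_country[bounds[c]:bounds[c + 1]] = c
    cell_country = cell_country.reshape(nlat, nlon)

    raw = rng.gamma(shape=2.0, scale=1.0, size=(nlat, nlon))
    weights = np.zeros((nlat, nlon))
    for c in range(cfg.n_countries):
        sel = cell_country == c
        weights[sel] = raw[sel] / raw[sel].sum()

    countries = tuple(f"C{c + 1:02d}" for c in range(cfg.n_countries))
    areas = {name: float(0.5 + rng.gamma(shape=2.0, scale=1.0))
             for name in countries}
    return CropMask(countries=countries, cell_country=cell_country,
                    weights=weights, areas=areas)


def generate_yields(climate: ClimateGrid, mask: CropMask, cfg: SyntheticConfig
                    ) -> Tuple[pd.DataFrame, dict]:
    """National yield series driven by the package's own HDD/SPEI pathway.

    log(yield_t) = log(base) + c1 t + c2 t^2
                   + s (gamma_spei SPEI*_t - gamma_hdd HDD_std*_t + e_t)

    with e_t ~ N(0, noise_sd). Returns the yield table and a ground-truth
    record (per-country predictor anomalies, noise, signal) for recovery
    tests.
    """
    if climate.grid_shape != cfg.grid_shape or mask.weights.shape != climate.tmax.shape[-2:]:
        raise ConfigurationError("climate, mask and config grids do not match")
    rng = _rng(cfg, 2)
    gamma_spei, gamma_hdd = cfg.yield_coeffs
    c1, c2 = cfg.trend_coeffs
    k, ending_month = cfg.yield_spei_window

    hdd_grid = hdd_jja(climate.tmax, cfg.t_thr)
    pet = thornthwaite_pet(climate.tmean, climate.lat)
    spei_cells, _ = spei_grid(climate.precip, pet, k, ending_month)

    t = np.arange(cfg.n_years, dtype=float)
    rows = []
    truth: dict = {
        "window": (k, ending_month),
        "gamma_spei": gamma_spei,
        "gamma_hdd": gamma_hdd,
        "signal_scale": cfg.signal_scale,
        "noise_sd": cfg.noise_sd,
        "countries": {},
    }
    for country in mask.countries:
        hdd_c = aggregate_to_country(hdd_grid, mask, country)
        spei_c = aggregate_to_country(spei_cells, mask, country)
        hdd_fit = fit_trend(cfg.years, hdd_c, transform="identity")
        spei_fit = fit_trend(cfg.years, spei_c, transform="identity")
        hdd_star = hdd_fit.anomalies(cfg.years, hdd_c, standardise=True)
        spei_star = spei_fit.anomalies(cfg.years, spei_c, standardise=False)
        noise = cfg.noise_sd * rng.standard_normal(cfg.n_years)
        signal = gamma_spei * spei_star - gamma_hdd * hdd_star
        log_yield = (np.log(cfg.base_yield) + c1 * t + c2 * t**2
                     + cfg.signal_scale * (signal + noise))
        yields = np.exp(log_yield)
        rows.append(pd.DataFrame({
            "country": country, "year": cfg.years, "yield": yields,
        }))
        truth["countries"][country] = {
            "spei_star": spei_star,
            "hdd_std_star": hdd_star,
            "noise": noise,
            "signal": signal,
        }
    return pd.concat(rows, ignore_index=True), truth


def generate_forecasts(climate: ClimateGrid, cfg: SyntheticConfig,
                       start_month: int = 5,
                       skill_rho: Optional[float] = None,
                       experiment: Optional[str] = None,
                       seed_tag: Optional[int] = None) -> EnsembleForecastGrid:
    """One ensemble re-forecast experiment over a 4-month lead window.

    Member deviations mix the observed deviation-from-climatology with
    independent member noise of the same law at correlation ``skill_rho``,
    then apply the configured bias shift and dispersion factor.
    """
    if start_month not in (5, 6):
        raise ConfigurationError("start_month must be 5 (May) or 6 (June)")
    rho = cfg.skill_rho if skill_rho is None else float(skill_rho)
    if not 0.0 <= rho <= 1.0:
        raise ConfigurationError(f"skill_rho must be in [0, 1]; got {rho}")
    months = tuple(range(start_month, start_month + 4))
    name = experiment or f"FC{start_month:02d}"
    tag = seed_tag if seed_tag is not None else 100 + start_month
    rng = _rng(cfg, tag)

    n_years = cfg.n_years
    mix = np.sqrt(max(0.0, 1.0 - rho**2))
    month_idx = [m - 1 for m in months]

    obs_tmean_dev = climate.tmean[:, month_idx] - climate.tmean_clim[None, month_idx]
    obs_precip_dev = climate.precip[:, month_idx] - climate.precip_clim[None, month_idx]
    obs_tmax_dev = (climate.tmax[:, JJA_START:JJA_STOP]
                    - climate.tmax_clim[None, JJA_START:JJA_STOP])

    m_tmean = np.empty((cfg.n_members,) + obs_tmean_dev.shape)
    m_precip = np.empty_like(m_tmean)
    m_tmax = np.empty((cfg.n_members,) + obs_tmax_dev.shape)
    for mem in range(cfg.n_members):
        nt, np_, nx = _draw_deviations(rng, cfg, months, n_years, jja_days=True)
        m_tmean[mem] = (climate.tmean_clim[None, month_idx] + cfg.bias_shift_temp
                        + cfg.dispersion_factor * (rho * obs_tmean_dev + mix * nt))
        m_precip[mem] = np.clip(
            climate.precip_clim[None, month_idx] + cfg.bias_shift_precip
            + cfg.dispersion_factor * (rho * obs_precip_dev + mix * np_),
            0.0, None)
        m_tmax[mem] = (climate.tmax_clim[None, JJA_START:JJA_STOP] + cfg.bias_shift_temp
                       + cfg.dispersion_factor * (rho * obs_tmax_dev + mix * nx))
    return EnsembleForecastGrid(
        experiment=name, start_month=start_month, months=months,
        years=climate.years, lat=climate.lat, lon=climate.lon,
        tmax_jja=m_tmax, tmean=m_tmean, precip=m_precip, skill_rho=rho,
    )


def generate_experiments(climate: ClimateGrid, cfg: SyntheticConfig
                         ) -> Dict[str, EnsembleForecastGrid]:
    """The four experiments: skilful (INIT-like) and skill-free (CLIM-like)
    land-surface initialisation, started in May and June."""
    out = {}
    for start_month in (5, 6):
        out[f"INIT{start_month:02d}"] = generate_forecasts(
            climate, cfg, start_month, skill_rho=cfg.skill_rho,
            experiment=f"INIT{start_month:02d}", seed_tag=100 + start_month)
        out[f"CLIM{start_month:02d}"] = generate_forecasts(
            climate, cfg, start_month, skill_rho=cfg.clim_skill_rho,
            experiment=f"CLIM{start_month:02d}", seed_tag=200 + start_month)
    return out
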