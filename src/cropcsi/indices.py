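"""Agro-climatic predictors: heat degree days and the SPEI drought index.

Heat degree days (HDD) over June-August measure the active temperature sum
above a conservative crop-damage threshold (default 30 degC, near the optimum
for maize growth processes):

    HDD_JJA = sum_i max(Tmax_i - T_thr, 0)

The standardised precipitation-evapotranspiration index (SPEI) standardises
the climatic water balance D = P - PET aggregated over k months by fitting a
three-parameter log-logistic distribution to the reference-period D values
with unbiased probability-weighted moments (PWM) and mapping through the
standard normal quantile function. Both indices are computed per grid cell
and then spatially averaged with harvested-crop-area weights to country level.

A fixed 365-day calendar (no leap days) is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import gamma as gamma_fn

from .errors import ConfigurationError, DataError, InsufficientDataError

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_START_DOY = np.concatenate([[0], np.cumsum(DAYS_IN_MONTH)])  # 0-based day index
#: mid-month day of year (1-based), used for solar declination
MID_MONTH_DOY = MONTH_START_DOY[:12] + DAYS_IN_MONTH // 2 + 1

JJA_START = int(MONTH_START_DOY[5])  # June 1, 0-based index into a 365-day year
JJA_STOP = int(MONTH_START_DOY[8])   # day after August 31


def compute_hdd_cell(tmax_daily: np.ndarray, t_thr: float = 30.0,
                     max_missing_frac: float = 0.05) -> float:
    """HDD for one cell-summer: sum of daily max-temperature exceedances.

    ``tmax_daily`` holds the June 1 - August 31 daily maxima of one year.
    NaNs are tolerated up to ``max_missing_frac`` of the summer and ignored.
    """
    x = np.asarray(tmax_daily, dtype=float)
    if not np.isfinite(t_thr):
        raise DataError("t_thr must be finite")
    missing = np.isnan(x)
    if missing.mean() > max_missing_frac:
        raise DataError(
            f"{missing.sum()} of {x.size} summer days missing exceeds tolerance"
        )
    return float(np.nansum(np.clip(x - t_thr, 0.0, None)))


def hdd_jja(tmax_daily: np.ndarray, t_thr: float = 30.0) -> np.ndarray:
    """Vectorised JJA heat degree days.

    ``tmax_daily`` has shape (..., 365, nlat, nlon); the summed exceedances
    are returned with shape (..., nlat, nlon).
    """
    summer = tmax_daily[..., JJA_START:JJA_STOP, :, :]
    return np.clip(summer - t_thr, 0.0, None).sum(axis=-3)


# ---------------------------------------------------------------------------
# Potential evapotranspiration
# ---------------------------------------------------------------------------

def _day_length_hours(lat_deg: np.ndarray, doy: np.ndarray) -> np.ndarray:
    """Astronomical day length (hours) from latitude and day of year."""
    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    decl = 0.4093 * np.sin(2.0 * np.pi * np.asarray(doy) / 365.0 - 1.405)
    cos_omega = np.clip(-np.tan(lat)[..., None] * np.tan(decl), -1.0, 1.0)
    omega = np.arccos(cos_omega)
    return 24.0 / np.pi * omega


def thornthwaite_pet(tmean_monthly: np.ndarray, lat_deg: np.ndarray,
                     heat_index: Optional[np.ndarray] = None) -> np.ndarray:
    """Monthly Thornthwaite PET (mm/month).

    ``tmean_monthly`` has shape (..., 12, nlat, nlon) (or (..., 12) with scalar
    latitude). Months with mean temperature <= 0 degC evaporate nothing. The
    annual heat index I is, by default, computed from the climatological
    monthly means (average over all leading axes), so a single I per cell is
    used for every year; this keeps observation- and forecast-side PET on one
    scale even when a forecast window covers only part of the year.
    """
    t = np.asarray(tmean_monthly, dtype=float)
    lat_deg = np.asarray(lat_deg, dtype=float)
    if np.any(np.abs(lat_deg) > 90):
        raise ConfigurationError("latitude outside [-90, 90]")

    tp = np.clip(t, 0.0, None)
    month_axis = -3 if t.ndim >= 3 else -1
    if heat_index is None:
        clim = tp
        while clim.ndim > (3 if t.ndim >= 3 else 1):
            clim = clim.mean(axis=0)
        heat_index = ((clim / 5.0) ** 1.514).sum(axis=month_axis)
    i_idx = np.asarray(heat_index, dtype=float)
    a = (6.75e-7 * i_idx**3 - 7.71e-5 * i_idx**2 + 1.792e-2 * i_idx + 0.49239)

    day_len = np.atleast_2d(_day_length_hours(lat_deg, MID_MONTH_DOY))  # (nlat, 12)
    if t.ndim >= 3:
        corr = (day_len.T[:, :, None] / 12.0) * (DAYS_IN_MONTH[:, None, None] / 30.0)
    else:
        corr = (day_len[0] / 12.0) * (DAYS_IN_MONTH / 30.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(i_idx > 0, 10.0 * tp / np.where(i_idx > 0, i_idx, 1.0), 0.0)
        pet = 16.0 * np.power(rel, a) * corr
    pet = np.where((tp > 0) & (i_idx > 0), pet, 0.0)
    return pet


def hargreaves_pet(tmean_monthly: np.ndarray, tmax_monthly: np.ndarray,
                   lat_deg: np.ndarray) -> np.ndarray:
    """Monthly Hargreaves PET (mm/month) from mean and maximum temperature.

    The diurnal range required by Hargreaves is approximated as
    2*(Tmax - Tmean); extraterrestrial radiation follows the FAO-56 formulas.
    Temperature-only alternative to Thornthwaite.
    """
    t = np.asarray(tmean_monthly, dtype=float)
    tx = np.asarray(tmax_monthly, dtype=float)
    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    if np.any(np.abs(lat_deg) > 90):
        raise ConfigurationError("latitude outside [-90, 90]")
    doy = MID_MONTH_DOY
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    cos_omega = np.clip(-np.tan(lat)[..., None] * np.tan(decl), -1.0, 1.0)
    omega = np.arccos(cos_omega)
    ra = (24.0 * 60.0 / np.pi) * 0.0820 * dr * (
        omega * np.sin(lat)[..., None] * np.sin(decl)
        + np.cos(lat)[..., None] * np.cos(decl) * np.sin(omega)
    )  # MJ m-2 day-1, shape (nlat, 12)
    ra_mm = ra * 0.408  # equivalent evaporation mm/day
    td = np.clip(2.0 * (tx - t), 0.0, None)
    if t.ndim >= 3:
        ra_b = ra_mm.T[:, :, None]
        ndays = DAYS_IN_MONTH[:, None, None]
    else:
        ra_b = ra_mm
        ndays = DAYS_IN_MONTH
    pet = 0.0023 * ra_b * (t + 17.8) * np.sqrt(td) * ndays
    return np.clip(pet, 0.0, None)


# ---------------------------------------------------------------------------
# SPEI
# ---------------------------------------------------------------------------

def _unbiased_pwm(x_sorted: np.ndarray) -> tuple[float, float, float]:
    """Unbiased PWM estimates a_s = E[X (1-F)^s], s = 0, 1, 2."""
    n = x_sorted.size
    i = np.arange(1, n + 1)
    a0 = x_sorted.mean()
    a1 = float(np.sum(x_sorted * (n - i)) / (n * (n - 1)))
    a2 = float(np.sum(x_sorted * (n - i) * (n - i - 1)) / (n * (n - 1) * (n - 2)))
    return float(a0), a1, a2


def fit_loglogistic_pwm(x: np.ndarray) -> Optional[tuple[float, float, float]]:
    """Fit the 3-parameter log-logistic F(x) = [1 + (alpha/(x-gamma))^beta]^-1.

    Returns (alpha, beta, gamma) estimated by unbiased probability-weighted
    moments, or ``None`` when the estimate is unusable (shape out of range or
    non-positive scale), in which case the caller falls back to an empirical
    plotting-position standardisation.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    if xs.size < 4 or not np.all(np.isfinite(xs)):
        return None
    w0, w1, w2 = _unbiased_pwm(xs)
    denom = 6.0 * w1 - w0 - 6.0 * w2
    if denom == 0:
        return None
    beta = (2.0 * w1 - w0) / denom
    if not np.isfinite(beta) or beta <= 1.0:
        return None  # Gamma(1 - 1/beta) requires beta > 1
    g = gamma_fn(1.0 + 1.0 / beta) * gamma_fn(1.0 - 1.0 / beta)
    alpha = (w0 - 2.0 * w1) * beta / g
    if not np.isfinite(alpha) or alpha <= 0:
        return None
    gamma_loc = w0 - alpha * g
    return float(alpha), float(beta), float(gamma_loc)


def loglogistic_cdf(x: np.ndarray, alpha: float, beta: float, gamma_loc: float) -> np.ndarray:
    """CDF of the fitted log-logistic; values at or below the origin map to ~0."""
    z = np.asarray(x, dtype=float) - gamma_loc
    out = np.zeros_like(z)
    pos = z > 0
    out[pos] = 1.0 / (1.0 + (alpha / z[pos]) ** beta)
    return out


@dataclass
class SpeiTransform:
    """Frozen water-balance -> SPEI mapping fitted on a reference sample.

    ``params`` holds (alpha, beta, gamma) of the log-logistic fit, or ``None``
    when the empirical Gringorten plotting-position fallback is in use; the
    sorted reference sample is kept for the fallback path. Probabilities are
    clipped away from 0/1 so the normal quantile stays finite.
    """

    params: Optional[tuple[float, float, float]]
    reference: np.ndarray

    _PCLIP = 5e-4

    def probabilities(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if not np.all(np.isfinite(d)):
            raise DataError("non-finite water balance values")
        if self.params is not None:
            p = loglogistic_cdf(d, *self.params)
        else:
            ref = self.reference
            n = ref.size
            pp = (np.arange(1, n + 1) - 0.44) / (n + 0.12)  # Gringorten
            p = np.interp(d, ref, pp)
        return np.clip(p, self._PCLIP, 1.0 - self._PCLIP)

    def __call__(self, d: np.ndarray) -> np.ndarray:
        return stats.norm.ppf(self.probabilities(d))


def fit_spei_transform(d_reference: np.ndarray) -> SpeiTransform:
    """Fit the standardisation transform on reference-period water balances."""
    ref = np.sort(np.asarray(d_reference, dtype=float))
    if ref.size < 20:
        raise InsufficientDataError(
            f"SPEI reference period needs >= 20 years; got {ref.size}"
        )
    if not np.all(np.isfinite(ref)):
        raise DataError("non-finite water balance in reference period")
    return SpeiTransform(params=fit_loglogistic_pwm(ref), reference=ref)


def aggregate_water_balance(precip_monthly: np.ndarray, pet_monthly: np.ndarray,
                            timescale: int, ending_month: int) -> np.ndarray:
    """k-month climatic water balance D ending at ``ending_month`` (1-based).

    Inputs have shape (n_years, 12, ...); the result drops the month axis.
    """
    if timescale not in (1, 2, 3):
        raise ConfigurationError(f"SPEI timescale must be 1, 2 or 3; got {timescale}")
    if not 1 <= ending_month <= 12 or ending_month - timescale < 0:
        raise ConfigurationError(
            f"window (k={timescale}, ending_month={ending_month}) leaves the calendar year"
        )
    d = np.asarray(precip_monthly, dtype=float) - np.asarray(pet_monthly, dtype=float)
    sl = slice(ending_month - timescale, ending_month)
    return d[:, sl, ...].sum(axis=1)


def compute_spei(precip_monthly: np.ndarray, pet_monthly: np.ndarray,
                 timescale: int, ending_month: int,
                 reference_idx: Optional[np.ndarray] = None
                 ) -> tuple[np.ndarray, SpeiTransform]:
    """SPEI series for one cell (or any 1-D aggregate).

    Inputs have shape (n_years, 12). Returns one SPEI value per year plus the
    fitted transform (reused later on bias-corrected forecast balances). The
    reference period defaults to all years.
    """
    d = aggregate_water_balance(precip_monthly, pet_monthly, timescale, ending_month)
    ref = d if reference_idx is None else d[reference_idx]
    transform = fit_spei_transform(ref)
    return transform(d), transform


def spei_grid(precip_monthly: np.ndarray, pet_monthly: np.ndarray,
              timescale: int, ending_month: int,
              reference_idx: Optional[np.ndarray] = None
              ) -> tuple[np.ndarray, dict]:
    """Per-cell SPEI over a grid.

    Inputs have shape (n_years, 12, nlat, nlon). Returns the SPEI field with
    shape (n_years, nlat, nlon) and a dict mapping (i, j) cell indices to the
    fitted :class:`SpeiTransform`, which is reused to standardise
    bias-corrected forecast water balances on the observed climatology.
    """
    d = aggregate_water_balance(precip_monthly, pet_monthly, timescale, ending_month)
    n_years, nlat, nlon = d.shape
    out = np.empty_like(d)
    transforms: dict = {}
    for i in range(nlat):
        for j in range(nlon):
            series = d[:, i, j]
            ref = series if reference_idx is None else series[reference_idx]
            tr = fit_spei_transform(ref)
            out[:, i, j] = tr(series)
            transforms[(i, j)] = tr
    return out, transforms


def spei_grid_apply(transforms: dict, d_field: np.ndarray) -> np.ndarray:
    """Apply previously fitted per-cell transforms to new water balances.

    ``d_field`` has shape (..., nlat, nlon) with the same grid the transforms
    were fitted on.
    """
    out = np.empty_like(np.asarray(d_field, dtype=float))
    nlat, nlon = d_field.shape[-2:]
    for i in range(nlat):
        for j in range(nlon):
            out[..., i, j] = transforms[(i, j)](d_field[..., i, j])
    return out


# ---------------------------------------------------------------------------
# Spatial aggregation
# ---------------------------------------------------------------------------

def aggregate_to_country(field: np.ndarray, mask, country: str) -> np.ndarray:
    """Crop-area-weighted spatial mean of ``field`` over one country.

    ``field`` has shape (..., nlat, nlon); ``mask`` is a
    :class:`cropcsi.synthetic.CropMask`. Weights are normalised within the
    country, so a uniform field aggregates to its own value.
    """
    w = mask.country_weights(country)
    total = w.sum()
    if total <= 0:
        raise ConfigurationError(f"country {country!r} has zero total crop weight")
    return np.tensordot(field, w / total, axes=([-2, -1], [0, 1]))
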