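"""Trend removal and standardisation of annual series.

National yield series carry decadal trends from changing agro-management and
technology; a quadratic polynomial in the (centred) year is fitted on
log(yield) and the residuals are the yield anomalies. Because this may also
strip part of the climate signal, the same de-trending is applied to the HDD
and SPEI series. Yield and HDD anomalies are additionally standardised to
unit variance; SPEI is de-trended only, being standardised by construction.
The Mann-Kendall test is reported as a trend diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import DegenerateSeriesError, DataError, InsufficientDataError


@dataclass
class MKResult:
    """Mann-Kendall trend test: S statistic, Kendall tau, two-sided p."""

    s: int
    tau: float
    p: float


def mann_kendall(series: np.ndarray) -> MKResult:
    """Mann-Kendall test with the tie-corrected normal approximation.

    S sums sign(x_j - x_i) over all ordered pairs i < j; under no trend its
    variance is n(n-1)(2n+5)/18 minus a correction for tied groups, and a
    continuity-corrected z gives the two-sided p-value.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 8:
        raise InsufficientDataError(f"Mann-Kendall needs n >= 8; got {n}")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite values in Mann-Kendall input")
    sgn = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(sgn, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    tie_term = np.sum(counts * (counts - 1) * (2 * counts + 5))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var_s <= 0:
        return MKResult(s=s, tau=0.0, p=1.0)
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    tau = s / (0.5 * n * (n - 1))
    return MKResult(s=s, tau=float(tau), p=float(p))


@dataclass
class TrendFit:
    """Quadratic trend fit on the (optionally log-) transformed scale.

    Coefficients are for the centred year t - t_mean, making the fit invariant
    to shifting the year origin. ``resid_sd`` (ddof=1) is stored so forecast
    anomalies can be standardised on the observation-derived scale.
    """

    transform: str                      # "log" or "identity"
    coefficients: tuple[float, float, float]  # (intercept, linear, quadratic)
    year_center: float
    resid_sd: float
    mk: Optional[MKResult] = None

    def _apply_transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.transform == "log":
            if np.any(values <= 0):
                raise DataError("log transform requires strictly positive values")
            return np.log(values)
        return values

    def predict(self, years: np.ndarray) -> np.ndarray:
        """Trend value on the transformed scale."""
        tc = np.asarray(years, dtype=float) - self.year_center
        c0, c1, c2 = self.coefficients
        return c0 + c1 * tc + c2 * tc**2

    def anomalies(self, years: np.ndarray, values: np.ndarray,
                  standardise: bool = False) -> np.ndarray:
        """Residuals from the trend; divided by ``resid_sd`` when standardising."""
        resid = self._apply_transform(values) - self.predict(years)
        if standardise:
            if self.resid_sd <= 1e-12 or not np.isfinite(self.resid_sd):
                raise DegenerateSeriesError("zero residual variance; cannot standardise")
            resid = resid / self.resid_sd
        return resid


def fit_trend(years: np.ndarray, values: np.ndarray, transform: str = "identity") -> TrendFit:
    """Least-squares quadratic trend in the centred year.

    ``transform='log'`` fits on log(values) (the yield pathway); HDD and SPEI
    use the identity scale since they can be zero or negative.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size != values.size:
        raise DataError("years and values must have equal length")
    if years.size < 5:
        raise InsufficientDataError(f"trend fit needs n >= 5; got {years.size}")
    if transform not in ("log", "identity"):
        raise DataError(f"unknown transform {transform!r}")
    if transform == "log":
        if np.any(values <= 0):
            raise DataError("log transform requires strictly positive values")
        yv = np.log(values)
    else:
        yv = values
    center = float(years.mean())
    tc = years - center
    design = np.column_stack([np.ones_like(tc), tc, tc**2])
    coef, *_ = np.linalg.lstsq(design, yv, rcond=None)
    resid = yv - design @ coef
    resid_sd = float(np.std(resid, ddof=1))
    mk = mann_kendall(yv) if years.size >= 8 else None
    return TrendFit(
        transform=transform,
        coefficients=(float(coef[0]), float(coef[1]), float(coef[2])),
        year_center=center,
        resid_sd=resid_sd,
        mk=mk,
    )


def detrend_standardise(years: np.ndarray, values: np.ndarray,
                        fit: Optional[TrendFit] = None,
                        transform: str = "identity",
                        standardise: bool = False,
                        detrend_if_mk_significant: bool = False,
                        mk_alpha: float = 0.05) -> np.ndarray:
    """De-trend (and optionally standardise) an annual series.

    With ``detrend_if_mk_significant`` the polynomial removal is applied only
    when the Mann-Kendall p-value falls below ``mk_alpha``; otherwise only the
    mean is removed (standardisation, when requested, still applies).
    """
    if fit is None:
        fit = fit_trend(years, values, transform=transform)
    if detrend_if_mk_significant and fit.mk is not None and fit.mk.p >= mk_alpha:
        yv = fit._apply_transform(values)
        resid = yv - yv.mean()
        sd = float(np.std(resid, ddof=1))
        if standardise:
            if sd <= 1e-12:
                raise DegenerateSeriesError("zero variance; cannot standardise")
            resid = resid / sd
        return resid
    return fit.anomalies(years, values, standardise=standardise)
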