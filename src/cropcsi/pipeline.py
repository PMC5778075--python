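"""End-to-end orchestration: observed calibration, forecast correction,
CSI re-forecast and probabilistic verification.

Countries are processed independently; all randomness (permutation nulls,
bootstrap resampling) is seeded from the analysis settings, so a rerun with
identical configuration reproduces identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .biascorrect import correct_field
from .config import AnalysisSettings
from .detrend import TrendFit, fit_trend
from .errors import ConfigurationError, ModelFailureError
from .indices import (
    aggregate_to_country,
    aggregate_water_balance,
    hargreaves_pet,
    hdd_jja,
    spei_grid,
    spei_grid_apply,
    thornthwaite_pet,
)
from .model import CSIModel, Q2Result, optimise_spei_choice, predict_csi, significance_test
from .synthetic import ClimateGrid, CropMask, EnsembleForecastGrid, JJA_MONTHS
from .verification import (
    VerificationReport,
    classify_stress_area,
    contingency_from_probs,
    correlation_skill,
    ensemble_csi,
    ets,
    event_probabilities,
    event_threshold,
    reliability_diagram,
    roc_and_rocss,
)

logger = logging.getLogger("cropcsi")


@dataclass
class CountryCalibration:
    """Observation-side calibration artefacts for one country."""

    model: CSIModel
    q2_result: Q2Result
    years: np.ndarray
    y_std: np.ndarray
    hdd_series: np.ndarray
    spei_series: np.ndarray          # chosen window, raw (pre-detrend)
    hdd_std_star: np.ndarray
    spei_star: np.ndarray
    yield_fit: TrendFit
    hdd_fit: TrendFit
    spei_fit: TrendFit
    csi_obs: np.ndarray
    threshold: float


@dataclass
class ObservedResults:
    """Everything the forecast stage needs from the observed calibration."""

    calibrations: Dict[str, CountryCalibration]
    excluded: Dict[str, str]
    q2_table: pd.DataFrame
    stress_fractions: pd.DataFrame
    spei_transforms: Dict[Tuple[int, int], dict]   # window -> per-cell transforms
    heat_index: np.ndarray                         # Thornthwaite I per cell
    settings: AnalysisSettings

    @property
    def significant_countries(self) -> list:
        return [c for c, cal in self.calibrations.items() if cal.model.significant]


def _compute_pet(climate: ClimateGrid, settings: AnalysisSettings,
                 heat_index: Optional[np.ndarray] = None) -> np.ndarray:
    if settings.pet_method == "thornthwaite":
        return thornthwaite_pet(climate.tmean, climate.lat, heat_index=heat_index)
    if settings.pet_method == "hargreaves":
        # monthly mean of daily maxima as the upper temperature
        from .indices import MONTH_START_DOY

        tmax_m = np.stack(
            [climate.tmax[:, MONTH_START_DOY[m]:MONTH_START_DOY[m + 1]].mean(axis=1)
             for m in range(12)], axis=1)
        return hargreaves_pet(climate.tmean, tmax_m, climate.lat)
    raise ConfigurationError(f"unknown PET method {settings.pet_method!r}")


def run_observed_analysis(climate: ClimateGrid, mask: CropMask,
                          yields: pd.DataFrame,
                          settings: Optional[AnalysisSettings] = None
                          ) -> ObservedResults:
    """Calibrate per-country CSI models from observed climate and yields.

    Chains index computation (HDD, the nine SPEI window candidates),
    de-trending/standardisation, SPEI-window optimisation by leave-one-out
    Q^2, and the permutation significance test. Countries with fewer than
    ``settings.min_years`` yield years, or without a usable model, are
    excluded with a logged reason.
    """
    settings = settings or AnalysisSettings()
    years = climate.years

    hdd_grid = hdd_jja(climate.tmax, settings.t_thr)
    tp = np.clip(climate.tmean.mean(axis=0), 0.0, None)
    heat_index = ((tp / 5.0) ** 1.514).sum(axis=0)
    pet = _compute_pet(climate, settings, heat_index=heat_index)

    windows = list(product(settings.spei_timescales, settings.spei_months))
    spei_fields: Dict[Tuple[int, int], np.ndarray] = {}
    spei_transforms: Dict[Tuple[int, int], dict] = {}
    for win in windows:
        spei_fields[win], spei_transforms[win] = spei_grid(
            climate.precip, pet, win[0], win[1])

    calibrations: Dict[str, CountryCalibration] = {}
    excluded: Dict[str, str] = {}
    q2_rows = []
    for ci, country in enumerate(mask.countries):
        sub = yields[yields["country"] == country].sort_values("year")
        yrs = sub["year"].to_numpy()
        common = np.isin(years, yrs)
        if common.sum() < settings.min_years:
            excluded[country] = (
                f"only {int(common.sum())} yield years; need >= {settings.min_years}"
            )
            logger.info("excluding %s: %s", country, excluded[country])
            continue
        idx = common
        yrs_c = years[idx]
        yvals = sub.set_index("year").loc[yrs_c, "yield"].to_numpy()

        yield_fit = fit_trend(yrs_c, yvals, transform="log")
        y_std = yield_fit.anomalies(yrs_c, yvals, standardise=True)

        hdd_c = aggregate_to_country(hdd_grid, mask, country)[idx]
        hdd_fit = fit_trend(yrs_c, hdd_c, transform="identity")
        hdd_star = hdd_fit.anomalies(yrs_c, hdd_c, standardise=True)

        candidates = {}
        cand_fits = {}
        for win in windows:
            series = aggregate_to_country(spei_fields[win], mask, country)[idx]
            cand_fit = fit_trend(yrs_c, series, transform="identity")
            candidates[win] = cand_fit.anomalies(yrs_c, series, standardise=False)
            cand_fits[win] = (series, cand_fit)

        try:
            model, q2_res = optimise_spei_choice(
                country, yrs_c, y_std, candidates, hdd_star,
                lambda_grid=settings.lambda_grid, min_years=settings.min_years)
        except ModelFailureError as exc:
            excluded[country] = str(exc)
            logger.info("excluding %s: %s", country, exc)
            continue

        rng = np.random.default_rng(
            np.random.SeedSequence([settings.seed, 1, ci]))
        sig, pval = significance_test(
            y_std, candidates[model.opt_choice], hdd_star, model.q2,
            model.ridge_lambda, n_perm=settings.perm_reps,
            alpha=settings.alpha, rng=rng)
        model.significant, model.p_value = sig, pval
        q2_res.significant, q2_res.p_value = sig, pval

        spei_series, spei_fit = cand_fits[model.opt_choice]
        spei_star = candidates[model.opt_choice]
        csi_obs = predict_csi(model, spei_star, hdd_star)
        calibrations[country] = CountryCalibration(
            model=model, q2_result=q2_res, years=yrs_c, y_std=y_std,
            hdd_series=hdd_c, spei_series=spei_series,
            hdd_std_star=hdd_star, spei_star=spei_star,
            yield_fit=yield_fit, hdd_fit=hdd_fit, spei_fit=spei_fit,
            csi_obs=csi_obs,
            threshold=event_threshold(csi_obs, settings.event_quantile),
        )
        q2_rows.append({
            "country": country, "q2": model.q2,
            "a": model.a, "b": model.b,
            "spei_timescale": model.opt_choice[0],
            "spei_ending_month": model.opt_choice[1],
            "ridge_lambda": model.ridge_lambda,
            "significant": sig, "p_value": pval,
        })

    q2_table = pd.DataFrame(
        q2_rows, columns=["country", "q2", "a", "b", "spei_timescale",
                          "spei_ending_month", "ridge_lambda", "significant",
                          "p_value"])

    sig_countries = [c for c, cal in calibrations.items() if cal.model.significant]
    if sig_countries:
        spei_mat = np.vstack([calibrations[c].spei_star for c in sig_countries])
        hdd_mat = np.vstack([calibrations[c].hdd_std_star for c in sig_countries])
        areas = np.array([mask.areas[c] for c in sig_countries])
        stress = classify_stress_area(spei_mat, hdd_mat, areas)
        stress.insert(0, "year", calibrations[sig_countries[0]].years)
    else:
        stress = pd.DataFrame(columns=["year", "drought_only", "heat_only", "combined"])

    return ObservedResults(
        calibrations=calibrations, excluded=excluded, q2_table=q2_table,
        stress_fractions=stress, spei_transforms=spei_transforms,
        heat_index=heat_index, settings=settings)


# ---------------------------------------------------------------------------
# Forecast side
# ---------------------------------------------------------------------------

def bias_correct_experiment(fc: EnsembleForecastGrid, climate: ClimateGrid,
                            settings: Optional[AnalysisSettings] = None
                            ) -> EnsembleForecastGrid:
    """Quantile-map the three forecast variables onto the observed climatology.

    Correction is stratified per variable, start month (one experiment is one
    start month), calendar month and grid cell, with members pooled. Daily
    maxima are corrected per calendar month with days pooled alongside
    members and years.
    """
    settings = settings or AnalysisSettings()
    nq = settings.n_quantiles
    from .indices import JJA_START, MONTH_START_DOY

    tmean_c = np.empty_like(fc.tmean)
    precip_c = np.empty_like(fc.precip)
    for mi, month in enumerate(fc.months):
        tmean_c[:, :, mi] = correct_field(
            fc.tmean[:, :, mi], climate.tmean[:, month - 1], n_quantiles=nq)
        precip_c[:, :, mi] = correct_field(
            fc.precip[:, :, mi], climate.precip[:, month - 1], n_quantiles=nq,
            floor_zero=True)
    tmax_c = np.empty_like(fc.tmax_jja)
    for month in JJA_MONTHS:
        d0 = int(MONTH_START_DOY[month - 1]) - JJA_START
        d1 = int(MONTH_START_DOY[month]) - JJA_START
        obs_days = climate.tmax[:, MONTH_START_DOY[month - 1]:MONTH_START_DOY[month]]
        tmax_c[:, :, d0:d1] = correct_field(
            fc.tmax_jja[:, :, d0:d1], obs_days, n_quantiles=nq)
    return EnsembleForecastGrid(
        experiment=fc.experiment, start_month=fc.start_month, months=fc.months,
        years=fc.years, lat=fc.lat, lon=fc.lon,
        tmax_jja=tmax_c, tmean=tmean_c, precip=precip_c,
        skill_rho=fc.skill_rho)


def _member_monthly_panel(fc: EnsembleForecastGrid, climate: ClimateGrid
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """Member monthly precip and tmean on a full 12-month axis.

    Months inside the lead window come from the (corrected) forecast; months
    before the forecast start are filled from the observations, which are
    known at initialisation time (needed by SPEI windows reaching back before
    the start month). Shapes: (members, years, 12, nlat, nlon).
    """
    n_members = fc.n_members
    shape = (n_members,) + climate.precip.shape
    precip = np.broadcast_to(climate.precip[None], shape).copy()
    tmean = np.broadcast_to(climate.tmean[None], shape).copy()
    for mi, month in enumerate(fc.months):
        precip[:, :, month - 1] = fc.precip[:, :, mi]
        tmean[:, :, month - 1] = fc.tmean[:, :, mi]
    return precip, tmean


def forecast_country_csi(fc: EnsembleForecastGrid, climate: ClimateGrid,
                         mask: CropMask, obs: ObservedResults, country: str
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Member-wise and ensemble-mean forecast CSI for one country.

    Member HDD and SPEI are computed from the (corrected) member fields,
    standardised with the observation-fitted SPEI transforms, trend fits and
    residual scales, and pushed through the observation-calibrated model.
    """
    cal = obs.calibrations[country]
    settings = obs.settings
    k, ending_month = cal.model.opt_choice

    member_hdd = np.clip(fc.tmax_jja - settings.t_thr, 0.0, None).sum(axis=2)
    hdd_c = aggregate_to_country(member_hdd, mask, country)
    hdd_anom = cal.hdd_fit.anomalies(fc.years, hdd_c, standardise=True)

    precip, tmean = _member_monthly_panel(fc, climate)
    pet = thornthwaite_pet(tmean, climate.lat, heat_index=obs.heat_index)
    n_members, n_years = precip.shape[:2]
    d = aggregate_water_balance(
        precip.reshape((-1,) + precip.shape[2:]),
        pet.reshape((-1,) + pet.shape[2:]), k, ending_month)
    d = d.reshape(n_members, n_years, *d.shape[1:])
    member_spei = spei_grid_apply(obs.spei_transforms[(k, ending_month)], d)
    spei_c = aggregate_to_country(member_spei, mask, country)
    spei_anom = cal.spei_fit.anomalies(fc.years, spei_c, standardise=False)

    return ensemble_csi(cal.model, spei_anom, hdd_anom)


def run_forecast_verification(obs: ObservedResults,
                              experiments: Dict[str, EnsembleForecastGrid],
                              climate: ClimateGrid, mask: CropMask,
                              bias_correct: bool = True
                              ) -> Dict[str, VerificationReport]:
    """Verify each re-forecast experiment against the observed CSI.

    Chains quantile mapping, member index computation, CSI prediction and the
    probabilistic scores, pooling countries with maize-cropland-area weights.
    Only countries with significant observed-climate models are scored.
    """
    settings = obs.settings
    countries = obs.significant_countries
    if not countries:
        raise ModelFailureError("no significant country models to verify")
    reports: Dict[str, VerificationReport] = {}
    for ei, (name, fc) in enumerate(sorted(experiments.items())):
        fc_c = bias_correct_experiment(fc, climate, settings) if bias_correct else fc
        probs_all, outcomes_all, weights_all = [], [], []
        rows_corr, rows_ets = [], []
        records = []
        for country in countries:
            cal = obs.calibrations[country]
            member_csi, mean_csi = forecast_country_csi(
                fc_c, climate, mask, obs, country)
            idx = np.isin(fc.years, cal.years)
            member_csi, mean_csi = member_csi[:, idx], mean_csi[idx]
            probs, outcomes = event_probabilities(
                member_csi, cal.csi_obs, cal.threshold)
            w = np.full(probs.size, mask.areas[country])
            probs_all.append(probs)
            outcomes_all.append(outcomes)
            weights_all.append(w)
            r1, p1, s1 = correlation_skill(mean_csi, cal.csi_obs, settings.alpha)
            r2, p2, s2 = correlation_skill(mean_csi, cal.y_std, settings.alpha)
            rows_corr.append({"country": country,
                              "r_csi": r1, "p_csi": p1, "sig_csi": s1,
                              "r_yield": r2, "p_yield": p2, "sig_yield": s2})
            row = {"country": country}
            for frac in settings.member_fractions:
                row[frac] = ets(contingency_from_probs(probs, outcomes, frac))
            rows_ets.append(row)
            for y, pr, oc in zip(cal.years, probs, outcomes):
                records.append({"country": country, "year": int(y),
                                "experiment": name, "prob": float(pr),
                                "outcome": bool(oc),
                                "weight": mask.areas[country]})

        probs = np.concatenate(probs_all)
        outcomes = np.concatenate(outcomes_all)
        weights = np.concatenate(weights_all)
        rng = np.random.default_rng(np.random.SeedSequence([settings.seed, 2, ei]))
        rel = reliability_diagram(
            probs, outcomes, weights, n_bins=settings.reliability_bins,
            n_boot=settings.n_boot, level=settings.boot_level, rng=rng)
        roc = roc_and_rocss(
            probs, outcomes, weights, threshold_step=settings.roc_step,
            n_boot=settings.n_boot, level=settings.boot_level, rng=rng)
        reports[name] = VerificationReport(
            experiment=name, reliability=rel, roc=roc,
            ets_table=pd.DataFrame(rows_ets).set_index("country"),
            correlations=pd.DataFrame(rows_corr),
            forecasts=pd.DataFrame(records))
        logger.info("%s: ROCSS=%.3f slope=%.3f", name, roc.rocss, rel.slope)
    return reports
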