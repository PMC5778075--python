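"""Probabilistic verification of low-yield CSI forecasts.

The low-yield event (CSI_low) is the observed-climate CSI falling below its
25th percentile over the study period, computed per country. Member-wise
forecast CSI values become event probabilities (fraction of members below the
threshold); pooled across countries with maize-cropland-area weights these are
scored with

* reliability diagrams (5 probability bins, count-weighted regression of
  observed frequency on forecast probability, pair-resampling bootstrap CI),
* ROC curves swept with a 20% decision-threshold step and the ROC skill score
  ROCSS = 2 * area - 1,
* the Equitable Threat Score ETS = (j - j_r) / (j + k + l - j_r) with the
  random-hit correction j_r = (j + l)(j + k) / (j + k + l + m), evaluated per
  country at member-fraction thresholds 50-80%,

plus Pearson correlation of ensemble-mean CSI with the observed series and a
three-way heat/drought stress-area classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, DegenerateSeriesError
from .model import CSIModel, predict_csi


# ---------------------------------------------------------------------------
# Contingency-table scores
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Hits j, false alarms k, misses l, correct negatives m."""

    j: float
    k: float
    l: float
    m: float

    def __post_init__(self) -> None:
        if min(self.j, self.k, self.l, self.m) < 0:
            raise DataError("contingency counts must be nonnegative")

    @property
    def n(self) -> float:
        return self.j + self.k + self.l + self.m


def ets(table: ContingencyTable) -> float:
    """Equitable Threat Score; NaN when the score is undefined (e.g. a table
    of correct negatives only)."""
    n = table.n
    if n == 0:
        return float("nan")
    j_r = (table.j + table.l) * (table.j + table.k) / n
    denom = table.j + table.k + table.l - j_r
    if denom == 0:
        return float("nan")
    return float((table.j - j_r) / denom)


def contingency_from_probs(probs: np.ndarray, outcomes: np.ndarray,
                           member_fraction: float) -> ContingencyTable:
    """Cross-tabulate forecast events (prob >= member_fraction) vs outcomes."""
    p = np.asarray(probs, float)
    o = np.asarray(outcomes, bool)
    fe = p >= member_fraction
    return ContingencyTable(
        j=float(np.sum(fe & o)),
        k=float(np.sum(fe & ~o)),
        l=float(np.sum(~fe & o)),
        m=float(np.sum(~fe & ~o)),
    )


# ---------------------------------------------------------------------------
# Event probabilities
# ---------------------------------------------------------------------------

def event_threshold(observed_csi: np.ndarray, quantile: float = 0.25) -> float:
    """Event threshold: empirical quantile (linear interpolation between order
    statistics) of the observed-climate CSI series."""
    return float(np.quantile(np.asarray(observed_csi, float), quantile))


def event_probabilities(member_csi: np.ndarray, observed_csi: np.ndarray,
                        threshold: float) -> Tuple[np.ndarray, np.ndarray]:
    """Per-year event probability and binary outcome.

    ``member_csi`` has shape (n_members, n_years); the probability is the
    fraction of members strictly below the threshold.
    """
    probs = np.mean(np.asarray(member_csi, float) < threshold, axis=0)
    outcomes = np.asarray(observed_csi, float) < threshold
    return probs, outcomes


def ensemble_csi(model: CSIModel, member_spei: np.ndarray,
                 member_hdd: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Member-wise CSI plus the ensemble mean (the model is linear, so the
    mean CSI equals the CSI of the member-mean indices)."""
    member_csi = predict_csi(model, member_spei, member_hdd)
    return member_csi, member_csi.mean(axis=0)


def correlation_skill(forecast: np.ndarray, reference: np.ndarray,
                      alpha: float = 0.05) -> Tuple[float, float, bool]:
    """Pearson r with two-sided t-test p-value and significance flag."""
    f = np.asarray(forecast, float)
    r_ = np.asarray(reference, float)
    if f.size < 10:
        raise DataError("correlation skill needs >= 10 paired years")
    if np.std(f) == 0 or np.std(r_) == 0:
        raise DegenerateSeriesError("constant series: correlation undefined")
    res = stats.pearsonr(f, r_)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


# ---------------------------------------------------------------------------
# Reliability diagram
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityResult:
    """Binned reliability with a count-weighted regression of observed
    frequency on forecast probability."""

    bin_prob: np.ndarray       # weighted mean forecast probability per bin
    bin_freq: np.ndarray       # weighted observed frequency per bin
    bin_weight: np.ndarray     # pooled (area) weight per bin
    slope: float
    intercept: float
    slope_ci: Tuple[float, float]
    climatology: float         # weighted observed base rate
    mean_forecast: float       # weighted mean forecast probability
    n_forecasts: int


def _binned_regression(probs: np.ndarray, outcomes: np.ndarray,
                       weights: np.ndarray, n_bins: int
                       ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    bp = np.full(n_bins, np.nan)
    bf = np.full(n_bins, np.nan)
    bw = np.zeros(n_bins)
    for b in range(n_bins):
        sel = idx == b
        w = weights[sel]
        if w.sum() > 0:
            bw[b] = w.sum()
            bp[b] = np.average(probs[sel], weights=w)
            bf[b] = np.average(outcomes[sel].astype(float), weights=w)
    ok = bw > 0
    if ok.sum() < 2 or np.ptp(bp[ok]) == 0:
        return bp, bf, bw, float("nan"), float("nan")
    coefs = np.polyfit(bp[ok], bf[ok], deg=1, w=np.sqrt(bw[ok]))
    return bp, bf, bw, float(coefs[0]), float(coefs[1])


def reliability_diagram(probs: np.ndarray, outcomes: np.ndarray,
                        weights: Optional[np.ndarray] = None,
                        n_bins: int = 5, n_boot: int = 1000,
                        level: float = 0.75,
                        rng: Optional[np.random.Generator] = None
                        ) -> ReliabilityResult:
    """Area-weighted reliability diagram pooled over countries.

    Empty bins carry zero weight and are excluded from the regression. The
    slope CI is a percentile interval from ``n_boot`` pair resamples.
    """
    probs = np.asarray(probs, float)
    outcomes = np.asarray(outcomes, bool)
    weights = np.ones_like(probs) if weights is None else np.asarray(weights, float)
    if probs.shape != outcomes.shape or probs.shape != weights.shape:
        raise DataError("probs, outcomes and weights must share a shape")
    rng = np.random.default_rng() if rng is None else rng
    bp, bf, bw, slope, intercept = _binned_regression(probs, outcomes, weights, n_bins)
    boot = np.empty(n_boot)
    n = probs.size
    for r in range(n_boot):
        take = rng.integers(0, n, size=n)
        *_, s, _ = _binned_regression(probs[take], outcomes[take], weights[take], n_bins)
        boot[r] = s
    boot = boot[np.isfinite(boot)]
    if boot.size < n_boot // 2:
        ci = (float("nan"), float("nan"))
    else:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        ci = (float(np.quantile(boot, lo)), float(np.quantile(boot, hi)))
    return ReliabilityResult(
        bin_prob=bp, bin_freq=bf, bin_weight=bw,
        slope=slope, intercept=intercept, slope_ci=ci,
        climatology=float(np.average(outcomes.astype(float), weights=weights)),
        mean_forecast=float(np.average(probs, weights=weights)),
        n_forecasts=int(n),
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    hit_rate: np.ndarray
    false_alarm_rate: np.ndarray
    thresholds: np.ndarray
    area: float
    rocss: float
    rocss_ci: Tuple[float, float] = (float("nan"), float("nan"))


def _roc_points(probs: np.ndarray, outcomes: np.ndarray, weights: np.ndarray,
                thresholds: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    pos = weights * outcomes
    neg = weights * (~outcomes)
    tp_total, fp_total = pos.sum(), neg.sum()
    if tp_total == 0 or fp_total == 0:
        raise DegenerateSeriesError("ROC needs both outcome classes present")
    hr = np.array([pos[probs >= t].sum() / tp_total for t in thresholds])
    far = np.array([neg[probs >= t].sum() / fp_total for t in thresholds])
    return hr, far


def roc_and_rocss(probs: np.ndarray, outcomes: np.ndarray,
                  weights: Optional[np.ndarray] = None,
                  threshold_step: float = 0.2,
                  n_boot: int = 0, level: float = 0.75,
                  rng: Optional[np.random.Generator] = None) -> RocResult:
    """ROC points from a probability-threshold sweep, trapezoid area closed at
    (0,0) and (1,1), and ROCSS = 2 * area - 1 (optionally bootstrapped)."""
    probs = np.asarray(probs, float)
    outcomes = np.asarray(outcomes, bool)
    weights = np.ones_like(probs) if weights is None else np.asarray(weights, float)
    thresholds = np.arange(threshold_step, 1.0 + 1e-9, threshold_step)[::-1]

    def _compute(p, o, w):
        hr, far = _roc_points(p, o, w, thresholds)
        far_c = np.concatenate([[0.0], far, [1.0]])
        hr_c = np.concatenate([[0.0], hr, [1.0]])
        order = np.argsort(far_c, kind="stable")
        area = float(np.trapezoid(hr_c[order], far_c[order]))
        return hr, far, area

    hr, far, area = _compute(probs, outcomes, weights)
    rocss = 2.0 * area - 1.0
    ci = (float("nan"), float("nan"))
    if n_boot > 0:
        rng = np.random.default_rng() if rng is None else rng
        vals = []
        n = probs.size
        for _ in range(n_boot):
            take = rng.integers(0, n, size=n)
            try:
                *_, a = _compute(probs[take], outcomes[take], weights[take])
            except DegenerateSeriesError:
                continue
            vals.append(2.0 * a - 1.0)
        if len(vals) >= n_boot // 2:
            lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
            ci = (float(np.quantile(vals, lo)), float(np.quantile(vals, hi)))
    return RocResult(hit_rate=hr, false_alarm_rate=far, thresholds=thresholds,
                     area=area, rocss=float(rocss), rocss_ci=ci)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(pairs: np.ndarray, statistic: Callable[[np.ndarray], float],
                 n_reps: int = 1000, level: float = 0.75,
                 rng: Optional[np.random.Generator] = None
                 ) -> Tuple[float, float]:
    """Percentile bootstrap interval of ``statistic`` over row resamples.

    Resamples with replacement from the rows of ``pairs`` (any per-forecast
    record array), skipping resamples where the statistic is undefined (NaN or
    raising); fails when more than half are undefined.
    """
    pairs = np.asarray(pairs)
    rng = np.random.default_rng() if rng is None else rng
    n = pairs.shape[0]
    vals = []
    for _ in range(n_reps):
        take = rng.integers(0, n, size=n)
        try:
            v = float(statistic(pairs[take]))
        except Exception:
            continue
        if np.isfinite(v):
            vals.append(v)
    if len(vals) < n_reps / 2:
        raise DataError("statistic undefined on more than half of the resamples")
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    return float(np.quantile(vals, lo)), float(np.quantile(vals, hi))


# ---------------------------------------------------------------------------
# Stress-area classification
# ---------------------------------------------------------------------------

def classify_stress_area(spei_star: np.ndarray, hdd_std_star: np.ndarray,
                         areas: np.ndarray) -> pd.DataFrame:
    """Annual fractions of maize area under drought-only, heat-only and
    combined stress.

    Categories (exclusive): drought only (SPEI* < -1 and HDD_std* < 1), heat
    only (SPEI* > -1 and HDD_std* > 1), combined (SPEI* < -1 and
    HDD_std* > 1). Inputs have shape (n_countries, n_years); ``areas`` holds
    the per-country maize production areas.
    """
    s = np.asarray(spei_star, float)
    h = np.asarray(hdd_std_star, float)
    a = np.asarray(areas, float)
    if s.shape != h.shape or s.shape[0] != a.size:
        raise ConfigurationError("spei, hdd and areas shapes do not match")
    total = a.sum()
    if total <= 0:
        raise ConfigurationError("zero total maize area")
    drought = (s < -1) & (h < 1)
    heat = (s > -1) & (h > 1)
    combined = (s < -1) & (h > 1)
    frac = lambda mask: (a[:, None] * mask).sum(axis=0) / total
    return pd.DataFrame({
        "drought_only": frac(drought),
        "heat_only": frac(heat),
        "combined": frac(combined),
    })


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    """Skill assessment of one re-forecast experiment."""

    experiment: str
    reliability: ReliabilityResult
    roc: RocResult
    ets_table: pd.DataFrame            # country x member_fraction ETS values
    correlations: pd.DataFrame         # per-country r/p vs obs CSI and yields
    forecasts: pd.DataFrame = field(repr=False)  # pooled (country, year, prob, outcome, weight)

    def summary(self) -> dict:
        return {
            "experiment": self.experiment,
            "n_forecasts": int(self.reliability.n_forecasts),
            "reliability_slope": self.reliability.slope,
            "reliability_slope_ci": list(self.reliability.slope_ci),
            "rocss": self.roc.rocss,
            "rocss_ci": list(self.roc.rocss_ci),
            "mean_corr_csi": float(self.correlations["r_csi"].mean()),
            "mean_ets": {
                str(c): float(np.nanmean(self.ets_table[c].to_numpy()))
                for c in self.ets_table.columns
            },
        }
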