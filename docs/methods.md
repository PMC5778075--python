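# Methods

This note documents the statistical procedures implemented in `cropcsi`,
their assumptions, the defaults that matter, and what the synthetic-data
generator does and does not emulate.

## Indices

**Heat degree days (HDD).** Per grid cell, the June–August sum of daily
maximum-temperature exceedances above a threshold (default 30 °C, a
conservative choice close to the optimum temperature for maize growth
processes, so the index accumulates damage over a wide super-optimal range).
A fixed 365-day calendar is used; a cell-summer with more than 5% missing
daily maxima is treated as invalid (`compute_hdd_cell` raises), keeping the
missing-data policy deterministic.

**Potential evapotranspiration.** Thornthwaite's temperature-only formulation
is the default: PET = 16 (10·T/I)^a · (L/12)(N/30) mm/month, zero for months
at or below 0 °C, with day length from latitude and mid-month solar
declination. The annual heat index I is computed from the *climatological*
monthly means (one value per cell), not per year. This choice keeps the
observation- and forecast-side PET on a single scale — a 4-month re-forecast
window cannot supply its own 12-month heat index — at the cost of ignoring
interannual variability in I, which is second-order for PET anomalies.
A Hargreaves variant (diurnal range approximated as 2·(Tmax − Tmean),
FAO-56 extraterrestrial radiation) is available via configuration.

**SPEI.** The climatic water balance D = P − PET is aggregated over k ∈
{1, 2, 3} months ending in June, July or August (all windows stay inside the
calendar year; the earliest month reached is April). A three-parameter
log-logistic distribution F(x) = [1 + (α/(x−γ))^β]^(−1) is fitted to the
reference-period D values by unbiased probability-weighted moments — the
standard SPEI formulation — and SPEI = Φ⁻¹(F(D)). The reference period is
the full analysis period. When the PWM estimate is unusable (β ≤ 1 or
non-positive scale) the implementation falls back to Gringorten
plotting-position standardisation. Probabilities are clipped to
[5·10⁻⁴, 1 − 5·10⁻⁴] so the normal quantile stays finite for balances
outside the fitted support; with 30-year references, more extreme
probabilities would be extrapolation anyway.

**Aggregation order.** Indices are computed per cell and *then* averaged to
country level with harvested-area weights normalised within each country.
Computing indices first preserves local extremes that averaging raw climate
would smooth. A consequence worth knowing: a country-average of per-cell
SPEI values has standard deviation slightly below 1 (averaging imperfectly
correlated standard normals), which the de-trending step does not undo —
SPEI is de-trended but never re-standardised.

## De-trending

Decadal trends (technology, management) are removed by least squares on a
quadratic in the centred year: on log(yield) for yields, on the identity
scale for HDD and SPEI (both can be zero or negative). Yield and HDD
anomalies are divided by their residual standard deviation (ddof = 1); SPEI
is de-trended only. The Mann–Kendall test (tie-corrected normal
approximation, continuity correction) is attached to every fit as a
diagnostic. De-trending is applied unconditionally by default — the
procedure stays deterministic and identical across countries — with an
optional mode that skips the polynomial (mean removal only) when the MK
p-value is above 0.05.

## CSI calibration

The model Y*_std = a·SPEI* + b·HDD*_std + ε is fitted intercept-free by
ridge regression on the centred anomalies. The penalty λ is selected from a
log-spaced grid (10⁻³ … 10², 6 values) by exact leave-one-out PRESS (the
hat-matrix shortcut) *inside each training fold*, so the reported Q² is a
nested cross-validation estimate with no selection leakage. The SPEI window
is chosen by maximising Q² over the nine candidates, scanned in
lexicographic (timescale, ending month) order with ties broken in favour of
the earlier candidate. Significance of Q² is a permutation test: the yield
series is permuted 500 times and Q² recomputed with the penalty held at the
observed fit's selection — holding λ makes the leave-one-out predictions
linear in y, so the whole null distribution is two matrix products — and the
model is significant when the observed Q² exceeds the 95th percentile of the
null. A Q² ≤ 0 is never significant. Countries with fewer than 20 yield
years, or with no usable candidate, are excluded.

## Bias correction

Non-parametric quantile mapping with 21 paired empirical quantiles at evenly
spaced probabilities, fitted per variable × start month × calendar month ×
grid cell with ensemble members pooled (daily maxima additionally pool the
days of the month). Transfer is piecewise linear between knots and a
constant offset beyond the outermost pair — bounded behaviour for unseen
extremes; corrected precipitation is floored at zero. The correction is
fitted in-sample over the full period. Monotonicity of the transfer
preserves member rank order within every stratum. One known consequence of
pooled empirical quantiles: even a forecast identical to the observations is
altered at O(1/n) by the differing interpolation positions of the pooled
(member-replicated) and observed samples; the exact perfect-forecast limit
therefore holds when the correction step is bypassed.

## Forecast CSI and verification

Member HDD and water balances are computed from corrected member fields;
months before the forecast start (needed by 2–3-month SPEI windows) are
filled from observations, which are available at initialisation time. Member
balances are standardised with the *observation-fitted* per-cell SPEI
transforms, and member indices converted to anomalies with the
observation-derived trend fits and residual scales, so forecast and observed
CSI live on one scale and one model serves both.

The low-yield event is CSI below its empirical 25th percentile (linear
interpolation between order statistics) of the observed-climate series, per
country. Event probability is the fraction of members below the threshold.
Verification pools countries with significant models, weighting by total
maize production area:

* **Reliability**: 5 equal-width probability bins; per-bin area-weighted
  mean forecast probability and observed frequency; regression of frequency
  on probability weighted by the pooled bin weights (area-weighted counts);
  slope uncertainty from a 1000-replicate pair-resampling bootstrap, 75%
  percentile interval.
* **ROC/ROCSS**: decision threshold stepped in 20% increments, curve closed
  at (0,0) and (1,1), trapezoid area, ROCSS = 2·area − 1, bootstrapped as
  above.
* **ETS**: per country and member-fraction threshold (50–80%), with the
  random-hit correction; tables with a zero denominator (e.g. all correct
  negatives) report the score as missing rather than a number.
* **Correlation**: Pearson r of ensemble-mean CSI with observed CSI and with
  standardised yield anomalies, two-sided t-test, no autocorrelation
  correction (annual series).

Stress-area classification uses the thresholds SPEI* < −1 (drought) and
HDD*_std > 1 (heat), three exclusive categories whose area fractions need
not sum to one (unstressed area remains).

## Synthetic generator

The generator emulates the structure the analysis assumes, with every choice
exposed in `SyntheticConfig`:

* **Climate**: harmonic seasonal cycles (July maximum-temperature
  climatology near 28 °C with a weak poleward gradient; summer precipitation
  minimum) plus monthly anomaly fields with exponential spatial correlation
  (e-folding length 6 cells), shared between daily-maximum and monthly-mean
  temperature; day-to-day tmax noise (1.5 °C) and cell-level precipitation
  noise (5 mm). Defaults (anomaly sds 1.5 °C and 15 mm) put summer maxima
  astride the 30 °C threshold, so HDD is zero in cool years and large in
  warm ones, and make drought and heat mildly co-vary through PET — both
  features of the real system.
* **Yields**: log(yield) = quadratic trend (1.5%/yr, slight levelling) plus
  0.15 × (0.4·SPEI* − 0.6·HDD*_std + N(0, 0.5)); the indices come from the
  package's own pathway, so the generating coefficients are recoverable and
  the overall yield CV lands near 15%, a realistic national figure. The 30
  year span mirrors the study-period length the inclusion rule (≥ 20 years)
  presumes.
* **Forecasts**: member deviation = ρ·(observed deviation) +
  √(1−ρ²)·(independent deviation of identical law), then an additive bias
  and multiplicative dispersion distortion. ρ = 1 reproduces the
  observations member-for-member; ρ = 0 yields a skill-free forecast with
  the observed climatology; the INIT/CLIM contrast is two values of ρ
  (default 0.8 vs 0.0) drawn from one observed truth, for May and June
  starts (4-month windows, both covering June–August).

What the generator does **not** emulate: daily precipitation, snow and soil
state, regime-dependent or lead-time-decaying forecast skill,
non-stationary variance, yield-record gaps and revisions, or any coupling of
crop management to climate. Passing tests therefore demonstrate that the
*methods* behave correctly under the assumed statistical structure — not
that real re-forecasts have skill.

## Numerical choices and problem sizes

Determinism throughout: every stochastic step derives from integer seed
sequences; regenerating with the same configuration is bit-identical.
Residual sds use ddof = 1; a residual sd ≤ 10⁻¹² is treated as degenerate.
Tie-breaks are lexicographic (smaller timescale, earlier month; smaller λ on
equal PRESS). Test and example problem sizes (grids of 3×3 to 6×6 cells,
1–3 countries, 30 or 200 years, 10 members) are chosen so the full suite
exercises every stage, including 100-replicate recovery studies and 200-year
skill-ordering runs, in about a minute; all statistical checks hold at these
sizes and the implementation is vectorised enough to scale to
continental grids.

## Known limitations

* The log-logistic PWM fit can fail for short or pathological references;
  the plotting-position fallback keeps SPEI defined but slightly
  less smooth in the tails.
* In-sample quantile mapping and in-sample SPEI reference fitting mean
  forecast skill estimates are marginally optimistic relative to a strict
  out-of-sample protocol; a leave-one-year-out correction mode would be the
  natural extension.
* The permutation null holds the ridge penalty fixed at the observed
  selection; re-selecting λ per permutation would be slower and, in the
  cases examined by the type-I-error test, does not change the rejection
  rate materially.
* Country processing is independent; no spatial pooling of coefficients
  across borders is attempted.
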