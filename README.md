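# cropcsi

Combined Stress Index (CSI) analysis for national crop-yield forecasting:
compute heat and drought stress indices over crop-masked regions, calibrate
country-level yield models with leave-one-out predictive optimisation,
bias-correct ensemble seasonal re-forecasts, and verify probabilistic
low-yield forecasts.

## The problem and for whom

Concurrent summer heat and drought drive most of the year-to-year variability
of European grain-maize yields. Agro-climatic analysts and seasonal-forecast
users need (i) a transparent statistical model linking national yield
anomalies to two interpretable stressors, and (ii) an honest, probabilistic
assessment of whether a seasonal forecasting system can anticipate low-yield
summers months ahead. `cropcsi` implements that pipeline as a tested Python
library. Because the original gridded observations, national yield records
and coupled-model re-forecasts are large and access-restricted, the package
ships a synthetic-data generator that reproduces their statistical structure
with known ground truth, so every stage is verifiable offline.

## The model

**Heat degree days** over June–August at each grid cell, with threshold
T_thr = 30 °C (near the optimum for maize growth processes):

    HDD_JJA = Σ_i max(T_max,i − T_thr, 0)

**SPEI** — the standardised precipitation-evapotranspiration index — is the
k-month climatic water balance D = P − PET (Thornthwaite PET by default),
standardised through a three-parameter log-logistic distribution fitted by
unbiased probability-weighted moments and mapped through Φ⁻¹.

Both indices are computed per cell, averaged to country level with
harvested-maize-area weights, de-trended (quadratic polynomial in the year,
applied on log(yield) for yields; Mann–Kendall reported as a diagnostic), and
standardised where appropriate. The **Combined Stress Index** then estimates
standardised yield anomalies:

    Y*_std,t = a · SPEI*_opt,t + b · HDD*_std,JJA,t + ε_t = CSI_t + ε_t

with (a, b) from a bilinear ridge regression and the SPEI window
(k ∈ {1,2,3} months, ending June–August) chosen per country by maximising
the leave-one-out cross-validated

    Q² = 1 − Σ_t (ŷ_t^(−t) − y_t)² / Σ_t (y_t − ȳ)²

A permutation test decides model significance. On the forecast side, ensemble
re-forecasts are quantile-mapped onto the observed climatology, pushed
through the observation-calibrated model, and the event "CSI below its
climatological 25th percentile" (CSI_low, a low-yield proxy) is verified
with reliability diagrams (5 bins, area-weighted), ROC / ROCSS
(2·AUC − 1, 20% threshold steps, 1000-replicate bootstrap 75% intervals)
and the Equitable Threat Score

    ETS = (j − j_r) / (j + k + l − j_r),   j_r = (j+l)(j+k) / (j+k+l+m).

## Worked example

```python
import cropcsi as cc

cfg = cc.SyntheticConfig(seed=42, grid_shape=(6, 6), n_countries=3)
climate = cc.generate_climate(cfg)
mask = cc.generate_crop_mask(cfg)
yields, truth = cc.generate_yields(climate, mask, cfg)   # truth: a=0.4, b=-0.6, SPEI2/July
obs = cc.run_observed_analysis(climate, mask, yields)
print(obs.q2_table.round(3).to_string(index=False))
```

prints

```
country    q2     a      b  spei_timescale  spei_ending_month  ridge_lambda  significant  p_value
    C01 0.718 0.440 -0.567               2                  7         1.000         True    0.002
    C02 0.557 0.390 -0.593               3                  8         0.100         True    0.002
    C03 0.671 0.585 -0.578               2                  7         0.001         True    0.002
```

i.e. the calibration recovers the generating coefficients (0.4, −0.6) and,
for two of three countries, the exact generating SPEI window (the third picks
a heavily overlapping one), with significant leave-one-out skill everywhere.
Verifying the four synthetic re-forecast experiments
(`examples/05_verify_forecasts.py`) gives

```
experiment   ROCSS  rel.slope  mean r(CSI)  mean ETS@60%
    INIT05   0.858      1.198        0.957         0.435
    INIT06   0.894      1.303        0.951         0.426
    CLIM05   0.098      0.275       -0.010         0.000
    CLIM06   0.077      0.299        0.037         0.021
```

— the skilful (INIT-like) initialisation discriminates low-yield years
(ROCSS ≈ 0.9) while the skill-free (CLIM-like) runs sit near zero, the
structural behaviour the verification stage is designed to expose.

The `examples/` directory contains one short narrative script per
capability; the `csi` console command (`csi synth | calibrate | correct |
verify | all`) runs the same stages from a YAML config with NetCDF/CSV/JSON
outputs.

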