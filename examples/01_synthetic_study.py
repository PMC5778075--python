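"""Generate a small synthetic study: climate grid, crop mask and yields.

The generator produces 30 years of gridded weather (daily maximum
temperature, monthly mean temperature and precipitation) with spatially
correlated interannual anomalies, splits the grid into countries with
harvested-area weights, and derives national maize yields whose log-scale
anomalies respond to drought (SPEI) and heat (HDD) with known coefficients.
"""

import cropcsi as cc

cfg = cc.SyntheticConfig(seed=42, grid_shape=(6, 6), n_countries=3)
climate = cc.generate_climate(cfg)
mask = cc.generate_crop_mask(cfg)
yields, truth = cc.generate_yields(climate, mask, cfg)

print(f"grid: {cfg.grid_shape}, years {cfg.years[0]}-{cfg.years[-1]}")
print(f"July mean tmax: {climate.tmax[:, 181:212].mean():.1f} degC "
      "(summer maxima straddle the 30 degC stress threshold)")

hdd = cc.hdd_jja(climate.tmax, cfg.t_thr)
print(f"heat degree days, grid mean per year: min {hdd.mean(axis=(1, 2)).min():.1f}, "
      f"max {hdd.mean(axis=(1, 2)).max():.1f} degC day")

for country in mask.countries:
    sub = yields[yields.country == country]["yield"]
    print(f"{country}: mean yield {sub.mean():.2f} t/ha, "
          f"CV {100 * sub.std() / sub.mean():.1f}% "
          f"(area weight {mask.areas[country]:.2f})")

print(f"\ngenerating signal: log-yield anomalies = "
      f"{truth['gamma_spei']} * SPEI* - {truth['gamma_hdd']} * HDD_std*, "
      f"SPEI window (k={truth['window'][0]}, ending month {truth['window'][1]}); "
      "downstream calibration should recover these.")
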