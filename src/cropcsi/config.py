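"""Configuration objects for the synthetic generator and the analysis pipeline.

The synthetic generator emulates the statistical structure a Combined Stress
Index (CSI) analysis consumes: a gridded European-style climate with a seasonal
cycle and spatially correlated interannual anomalies, crop-area weight grids,
national maize yields with a quadratic technology trend and a known linear
climate signal, and ensemble seasonal re-forecasts whose correlation with the
observed anomalies, mean bias and spread are tunable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np
import yaml

from .errors import ConfigurationError


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults describe a 30-year study period (mirroring a 1981-2010 analysis
    window), a 10x10 grid split into 4 countries, and a 10-member re-forecast
    ensemble. ``yield_coeffs = (gamma_spei, gamma_hdd)`` are standardised
    effect sizes; SPEI enters the log-yield signal positively (wetter than
    normal helps) and HDD negatively (heat hurts).
    """

    n_years: int = 30
    start_year: int = 1981
    grid_shape: Tuple[int, int] = (10, 10)
    n_countries: int = 4
    n_members: int = 10

    # forecast skill/distortion knobs
    skill_rho: float = 0.8       # INIT-like experiment
    clim_skill_rho: float = 0.0  # CLIM-like experiment
    bias_shift_temp: float = 0.0     # deg C added to forecast tmax/tmean
    bias_shift_precip: float = 0.0   # mm/month added to forecast precip
    dispersion_factor: float = 1.0   # multiplicative member-anomaly spread

    # yield model: log(yield) = log(base) + c1*t + c2*t^2 + s*(signal + noise)
    yield_coeffs: Tuple[float, float] = (0.4, 0.6)   # (gamma_spei, gamma_hdd)
    trend_coeffs: Tuple[float, float] = (0.015, -0.0001)
    noise_sd: float = 0.5
    signal_scale: float = 0.15
    base_yield: float = 6.0                          # t/ha
    yield_spei_window: Tuple[int, int] = (2, 7)      # (timescale k, ending month)

    # climate variability
    t_anom_sd: float = 1.5        # deg C, monthly spatially correlated anomaly
    p_anom_sd: float = 15.0       # mm/month, monthly spatially correlated anomaly
    daily_noise_sd: float = 1.5   # deg C, day-to-day tmax noise
    p_cell_noise_sd: float = 5.0  # mm/month, cell-level precip noise
    spatial_corr_length: float = 6.0  # e-folding distance in grid cells

    # grid geometry
    lat0: float = 40.0
    dlat: float = 1.0
    lon0: float = 0.0
    dlon: float = 1.0

    t_thr: float = 30.0  # deg C HDD threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 20:
            raise ConfigurationError(
                f"n_years must be >= 20 (study inclusion rule); got {self.n_years}"
            )
        nlat, nlon = self.grid_shape
        if nlat < 1 or nlon < 1:
            raise ConfigurationError(f"invalid grid_shape {self.grid_shape}")
        if self.n_countries < 1 or self.n_members < 1:
            raise ConfigurationError("n_countries and n_members must be positive")
        if self.n_countries > nlat * nlon:
            raise ConfigurationError(
                f"n_countries={self.n_countries} exceeds number of grid cells {nlat * nlon}"
            )
        for rho in (self.skill_rho, self.clim_skill_rho):
            if not 0.0 <= rho <= 1.0:
                raise ConfigurationError(f"skill_rho must be in [0, 1]; got {rho}")
        if self.noise_sd < 0 or self.dispersion_factor <= 0:
            raise ConfigurationError("noise_sd must be >= 0 and dispersion_factor > 0")
        k, m = self.yield_spei_window
        if k not in (1, 2, 3) or m not in (6, 7, 8):
            raise ConfigurationError(
                f"yield_spei_window must be (k in 1..3, month in 6..8); got {(k, m)}"
            )

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("grid_shape", "yield_coeffs", "trend_coeffs", "yield_spei_window"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("grid_shape", "yield_coeffs", "trend_coeffs", "yield_spei_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class AnalysisSettings:
    """Knobs of the analysis itself (as opposed to the synthetic inputs).

    ``lambda_grid`` is the ridge-penalty candidate grid searched by inner
    leave-one-out within every training fold; ``event_quantile`` defines the
    low-yield event (CSI below its climatological quartile).
    """

    t_thr: float = 30.0
    pet_method: str = "thornthwaite"
    spei_timescales: Tuple[int, ...] = (1, 2, 3)
    spei_months: Tuple[int, ...] = (6, 7, 8)
    lambda_grid: Tuple[float, ...] = tuple(np.logspace(-3, 2, 6))
    min_years: int = 20
    detrend_if_mk_significant: bool = False
    mk_alpha: float = 0.05
    perm_reps: int = 500
    alpha: float = 0.05
    event_quantile: float = 0.25
    member_fractions: Tuple[float, ...] = (0.5, 0.6, 0.7, 0.8)
    roc_step: float = 0.2
    reliability_bins: int = 5
    n_boot: int = 1000
    boot_level: float = 0.75
    n_quantiles: int = 21
    seed: int = 12345

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("spei_timescales", "spei_months", "lambda_grid", "member_fractions"):
            d[key] = [float(v) for v in d[key]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisSettings":
        d = dict(d)
        for key, typ in (
            ("spei_timescales", int),
            ("spei_months", int),
            ("lambda_grid", float),
            ("member_fractions", float),
        ):
            if key in d:
                d[key] = tuple(typ(v) for v in d[key])
        return cls(**d)


@dataclass
class PipelineConfig:
    """Full run configuration: synthetic inputs plus analysis settings."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def to_dict(self) -> dict:
        return {"synthetic": self.synthetic.to_dict(), "analysis": self.analysis.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            synthetic=SyntheticConfig.from_dict(d.get("synthetic", {})),
            analysis=AnalysisSettings.from_dict(d.get("analysis", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
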