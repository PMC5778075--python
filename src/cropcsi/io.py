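"""Standard-format I/O: NetCDF grids, CSV tables, JSON models and reports.

Grids are written as CF-style NetCDF (lat/lon/time dimensions) through
xarray's scipy backend; every file carries provenance attributes (package
version, seed, configuration hash).
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, Optional

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .model import CSIModel
from .synthetic import ClimateGrid, CropMask, EnsembleForecastGrid

_ENGINE = "scipy"  # NetCDF3 classic; no external netCDF library required


def config_hash(config_dict: dict) -> str:
    payload = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _provenance(seed: Optional[int] = None, cfg_hash: Optional[str] = None) -> dict:
    attrs = {"package": f"cropcsi {__version__}"}
    if seed is not None:
        attrs["seed"] = int(seed)
    if cfg_hash is not None:
        attrs["config_hash"] = cfg_hash
    return attrs


def write_climate(climate: ClimateGrid, path, **prov) -> None:
    ds = xr.Dataset(
        {
            "tmax": (("year", "doy", "lat", "lon"), climate.tmax.astype("f4")),
            "tmean": (("year", "month", "lat", "lon"), climate.tmean),
            "precip": (("year", "month", "lat", "lon"), climate.precip),
            "tmax_clim": (("doy", "lat", "lon"), climate.tmax_clim),
            "tmean_clim": (("month", "lat", "lon"), climate.tmean_clim),
            "precip_clim": (("month", "lat", "lon"), climate.precip_clim),
        },
        coords={
            "year": climate.years,
            "doy": np.arange(1, 366),
            "month": np.arange(1, 13),
            "lat": climate.lat,
            "lon": climate.lon,
        },
        attrs={
            "title": "synthetic gridded climate (tmax degC daily; tmean degC, "
                     "precip mm/month monthly)",
            **_provenance(**prov),
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_climate(path) -> ClimateGrid:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        return ClimateGrid(
            years=ds["year"].values,
            lat=ds["lat"].values, lon=ds["lon"].values,
            tmax=ds["tmax"].values.astype(float),
            tmean=ds["tmean"].values,
            precip=ds["precip"].values,
            tmax_clim=ds["tmax_clim"].values,
            tmean_clim=ds["tmean_clim"].values,
            precip_clim=ds["precip_clim"].values,
        )


def write_forecast(fc: EnsembleForecastGrid, path, **prov) -> None:
    ds = xr.Dataset(
        {
            "tmax_jja": (("member", "year", "jja_day", "lat", "lon"),
                         fc.tmax_jja.astype("f4")),
            "tmean": (("member", "year", "lead_month", "lat", "lon"), fc.tmean),
            "precip": (("member", "year", "lead_month", "lat", "lon"), fc.precip),
        },
        coords={
            "member": np.arange(1, fc.n_members + 1),
            "year": fc.years,
            "jja_day": np.arange(fc.tmax_jja.shape[2]),
            "lead_month": list(fc.months),
            "lat": fc.lat,
            "lon": fc.lon,
        },
        attrs={
            "experiment": fc.experiment,
            "start_month": fc.start_month,
            "skill_rho": fc.skill_rho,
            **_provenance(**prov),
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_forecast(path) -> EnsembleForecastGrid:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        return EnsembleForecastGrid(
            experiment=str(ds.attrs["experiment"]),
            start_month=int(ds.attrs["start_month"]),
            months=tuple(int(m) for m in ds["lead_month"].values),
            years=ds["year"].values,
            lat=ds["lat"].values, lon=ds["lon"].values,
            tmax_jja=ds["tmax_jja"].values.astype(float),
            tmean=ds["tmean"].values,
            precip=ds["precip"].values,
            skill_rho=float(ds.attrs["skill_rho"]),
        )


def write_mask(mask: CropMask, path, **prov) -> None:
    nlat, nlon = mask.weights.shape
    ds = xr.Dataset(
        {
            "cell_country": (("lat_idx", "lon_idx"), mask.cell_country),
            "weights": (("lat_idx", "lon_idx"), mask.weights),
        },
        coords={"lat_idx": np.arange(nlat), "lon_idx": np.arange(nlon)},
        attrs={
            "countries": json.dumps(list(mask.countries)),
            "areas": json.dumps(mask.areas),
            **_provenance(**prov),
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_mask(path) -> CropMask:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        return CropMask(
            countries=tuple(json.loads(ds.attrs["countries"])),
            cell_country=ds["cell_country"].values,
            weights=ds["weights"].values,
            areas={k: float(v) for k, v in json.loads(ds.attrs["areas"]).items()},
        )


def write_yields(yields: pd.DataFrame, path) -> None:
    yields.to_csv(path, index=False)


def read_yields(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj: dict, path, **prov) -> None:
    payload = {"provenance": _provenance(**prov), **_jsonable(obj)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_models(models: Dict[str, CSIModel], path, **prov) -> None:
    write_json({"models": {c: m.to_dict() for c, m in models.items()}}, path, **prov)


def read_models(path) -> Dict[str, CSIModel]:
    with open(path) as fh:
        payload = json.load(fh)
    return {c: CSIModel.from_dict(d) for c, d in payload["models"].items()}
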