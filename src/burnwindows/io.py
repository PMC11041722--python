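"""Readers and writers: CF NetCDF grids, burn-plan JSON, regional CSV.

NetCDF files are written through xarray's scipy backend (NETCDF3_CLASSIC),
so booleans are stored as flagged int8 and times as integer days since a
reference date.  Readers normalize units to the package's SI conventions
(degC, %, m/s, mm) from the units attributes, and longitudes to 0-360 degE.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .prescriptions import BurnPlan, PrescriptionEnvelope
from .synthetic import WEATHER_VARS, validate_weather

__all__ = [
    "write_weather_netcdf",
    "read_weather_netcdf",
    "write_bool_netcdf",
    "read_bool_netcdf",
    "write_fm_netcdf",
    "read_fm_netcdf",
    "plans_to_json",
    "plans_from_json",
    "envelope_to_dict",
    "write_regional_csv",
]

_ENGINE = "scipy"
_TIME_ENC = {"units": "days since 1900-01-01", "dtype": "int32", "calendar": "proleptic_gregorian"}


def _to_netcdf(ds: xr.Dataset, path) -> None:
    enc = {}
    if "time" in ds.coords:
        enc["time"] = dict(_TIME_ENC)
    for name, var in ds.data_vars.items():
        if var.dtype == bool:
            ds[name] = var.astype("int8")
            ds[name].attrs["flag_values"] = "0: false, 1: true"
    ds.to_netcdf(path, engine=_ENGINE, encoding=enc)


def write_weather_netcdf(weather: xr.Dataset, path) -> None:
    _to_netcdf(weather, path)


_UNIT_CONVERSIONS = {
    # canonical unit -> {alias: converter}
    "degC": {"k": lambda x: x - 273.15, "kelvin": lambda x: x - 273.15,
             "degf": lambda x: (x - 32.0) * 5.0 / 9.0},
    "m s-1": {"km h-1": lambda x: x / 3.6, "kph": lambda x: x / 3.6},
    "mm": {"m": lambda x: x * 1000.0, "cm": lambda x: x * 10.0},
    "%": {"1": lambda x: x * 100.0, "fraction": lambda x: x * 100.0},
}

_CANONICAL_UNITS = {"tmax": "degC", "tmin": "degC", "rhmax": "%", "rhmin": "%",
                    "wind10": "m s-1", "precip": "mm"}


def _normalize_units(da: xr.DataArray, canonical: str) -> xr.DataArray:
    units = str(da.attrs.get("units", canonical)).strip()
    key = units.lower().replace("_", " ").replace("/", " ").replace("degrees", "deg")
    canon_key = canonical.lower()
    if key in (canon_key, canon_key.replace(" ", ""), "deg c" if canonical == "degC" else canon_key):
        out = da
    else:
        table = _UNIT_CONVERSIONS.get(canonical, {})
        if key not in table:
            raise ValueError(f"variable {da.name!r}: cannot convert units {units!r} "
                             f"to {canonical!r}")
        out = table[key](da)
    out = out.assign_attrs(units=canonical)
    return out


def read_weather_netcdf(path) -> xr.Dataset:
    """Read and validate a daily weather grid, normalizing units and longitudes."""
    ds = xr.open_dataset(path, engine=_ENGINE).load()
    missing = [v for v in WEATHER_VARS if v not in ds]
    if missing:
        raise ValueError(f"weather file {path} is missing variables: {missing}")
    for name in WEATHER_VARS:
        ds[name] = _normalize_units(ds[name], _CANONICAL_UNITS[name])
    lon = ds["lon"].values % 360.0
    if not np.array_equal(lon, ds["lon"].values):
        ds = ds.assign_coords(lon=lon).sortby("lon")
    validate_weather(ds)
    return ds


def write_fm_netcdf(fm: xr.Dataset, path) -> None:
    out = fm.copy()
    if "usable" in out.coords:
        out = out.reset_coords("usable")
        out["usable"] = out["usable"].astype("int8")
    _to_netcdf(out, path)


def read_fm_netcdf(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine=_ENGINE).load()
    if "usable" in ds:
        ds = ds.set_coords("usable")
        ds = ds.assign_coords(usable=ds["usable"].astype(bool))
    return ds


def write_bool_netcdf(da: xr.DataArray, path) -> None:
    """Store a boolean day grid (RxDays, stagnation days) as flagged int8."""
    _to_netcdf(da.to_dataset(name=da.name or "flag"), path)


def read_bool_netcdf(path, name: str) -> xr.DataArray:
    ds = xr.open_dataset(path, engine=_ENGINE).load()
    return ds[name].astype(bool)


# ---------------------------------------------------------------------------
# burn plans / envelopes (JSON)


def plans_to_json(plans, path) -> None:
    payload = [{"id": p.identifier, "veg_class": p.veg_class,
                "bounds": {v: list(b) for v, b in p.bounds.items()}}
               for p in plans]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def plans_from_json(path) -> list[BurnPlan]:
    payload = json.loads(Path(path).read_text())
    return [BurnPlan(identifier=item["id"], veg_class=item["veg_class"],
                     bounds={v: tuple(b) for v, b in item["bounds"].items()})
            for item in payload]


def envelope_to_dict(env: PrescriptionEnvelope) -> dict:
    return {"veg_class": env.veg_class,
            "bounds": {v: list(b) for v, b in env.bounds.items()},
            "provenance": list(env.provenance)}


def write_regional_csv(frame: pd.DataFrame, path) -> None:
    """Regional series as CSV with a stable column order and float format."""
    cols = [c for c in ("year", "season", "region", "value") if c in frame.columns]
    frame = frame[cols + [c for c in frame.columns if c not in cols]]
    frame.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
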