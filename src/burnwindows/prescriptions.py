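"""Burn-plan envelopes and binary "in prescription" (RxDay) classification.

A burn plan states, per environmental variable, the [lower, upper] range
within which a prescribed fire meets objectives and remains controllable.
Plans are pooled by vegetation class (forest vs non-forest; only forest
plans constrain the 100-h/1000-h heavy-fuel moistures) into a median
envelope: the per-variable median of the plans' lower bounds paired with the
median of their upper bounds.  A grid-cell day is an RxDay when every
bounded variable lies inside its envelope — evaluated at peak-burn
conditions (daily maximum temperature, daily minimum relative humidity,
mid-flame wind scaled from the daily-mean 10 m wind).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import xarray as xr

__all__ = [
    "VEG_FOREST",
    "VEG_NONFOREST",
    "HEAVY_FM_VARS",
    "FM_VARS",
    "RX_VARIANTS",
    "BurnPlan",
    "PrescriptionEnvelope",
    "median_envelope",
    "midflame_wind",
    "daily_evaluation_vector",
    "classify_rxday",
    "rxday_grid",
]

VEG_FOREST = "forest"
VEG_NONFOREST = "non-forest"

#: heavy (large-diameter) dead-fuel moisture classes, absent from non-forest plans
HEAVY_FM_VARS = frozenset({"fm100", "fm1000"})
#: all fuel-moisture / fire-danger variables (dropped by the meteorology-only variant)
FM_VARS = frozenset({"fm1", "fm10", "fm100", "fm1000", "ignition_component"})

EVAL_VARS = ("temp", "rh", "midflame_wind", "fm1", "fm10", "fm100", "fm1000",
             "ignition_component")

RX_VARIANTS = ("veg_aware", "forest_uniform", "nonforest_uniform",
               "allplans_uniform", "no_fuel_moisture", "no_heavy_fuel_moisture")

#: daily-mean to afternoon-peak wind scaling
DIURNAL_WIND_FACTOR = 1.5
#: 10 m to mid-flame height frictional reduction
MIDFLAME_WIND_FACTOR = 0.4


@dataclass(frozen=True)
class BurnPlan:
    """One burn plan: a vegetation class and per-variable acceptable ranges.

    Units: temp degC, rh %, midflame_wind m/s, fuel moistures % of dry
    weight, ignition_component dimensionless index 0-100.
    """

    identifier: str
    veg_class: str
    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.veg_class not in (VEG_FOREST, VEG_NONFOREST):
            raise ValueError(f"unknown vegetation class {self.veg_class!r}")
        for var, (lo, hi) in self.bounds.items():
            if var not in EVAL_VARS:
                raise ValueError(f"plan {self.identifier!r}: unknown variable {var!r}")
            if not lo < hi:
                raise ValueError(
                    f"plan {self.identifier!r}: lower bound {lo} must be below "
                    f"upper bound {hi} for {var!r}")
        if self.veg_class == VEG_NONFOREST and HEAVY_FM_VARS & set(self.bounds):
            raise ValueError(
                f"plan {self.identifier!r}: non-forest plans never carry "
                "100-h/1000-h fuel-moisture criteria")


@dataclass(frozen=True)
class PrescriptionEnvelope:
    """Median [lower, upper] bounds per variable for one vegetation class."""

    veg_class: str
    bounds: Mapping[str, tuple[float, float]]
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def drop(self, vars_to_drop: frozenset[str] | set[str]) -> "PrescriptionEnvelope":
        kept = {v: b for v, b in self.bounds.items() if v not in vars_to_drop}
        return PrescriptionEnvelope(self.veg_class, kept, self.provenance)


def median_envelope(plans: Sequence[BurnPlan],
                    veg_class: str | None = None) -> PrescriptionEnvelope:
    """Median of lower bounds and median of upper bounds, per variable.

    Variables present in only some plans use the median over the plans that
    include them.  With ``veg_class=None`` all plans are pooled (the
    all-plans sensitivity definition, labelled "all").
    """
    if veg_class is not None:
        selected = [p for p in plans if p.veg_class == veg_class]
        if any(p.veg_class not in (VEG_FOREST, VEG_NONFOREST) for p in plans):
            raise ValueError("plans contain an unknown vegetation class")
    else:
        selected = list(plans)
    if not selected:
        raise ValueError(f"no plans available for class {veg_class!r}")
    variables = sorted({v for p in selected for v in p.bounds})
    bounds = {}
    for var in variables:
        lowers = [p.bounds[var][0] for p in selected if var in p.bounds]
        uppers = [p.bounds[var][1] for p in selected if var in p.bounds]
        bounds[var] = (float(np.median(lowers)), float(np.median(uppers)))
    return PrescriptionEnvelope(veg_class or "all", bounds,
                                tuple(p.identifier for p in selected))


def midflame_wind(wind10_daily_mean):
    """Daily-mean 10 m wind -> mid-flame wind: x1.5 afternoon peak, x0.4 friction."""
    wind = np.asarray(wind10_daily_mean, float) if not isinstance(
        wind10_daily_mean, xr.DataArray) else wind10_daily_mean
    if bool(np.any(np.asarray(wind) < 0)):
        raise ValueError("wind speed must be nonnegative")
    return wind * (DIURNAL_WIND_FACTOR * MIDFLAME_WIND_FACTOR)


def daily_evaluation_vector(weather: xr.Dataset, fm: xr.Dataset) -> xr.Dataset:
    """Assemble the per-cell-day variables against which envelopes are checked.

    Uses peak-burn values: daily maximum temperature, daily minimum relative
    humidity and the mid-flame wind derived from the daily-mean 10 m wind,
    alongside the fuel-moisture and ignition-component fields.
    """
    for axis in ("time", "lat", "lon"):
        if not np.array_equal(weather[axis].values, fm[axis].values):
            raise ValueError(f"weather and fuel-moisture grids disagree on {axis!r}")
    ds = xr.Dataset({
        "temp": weather["tmax"],
        "rh": weather["rhmin"],
        "midflame_wind": midflame_wind(weather["wind10"]),
        "fm1": fm["fm1"],
        "fm10": fm["fm10"],
        "fm100": fm["fm100"],
        "fm1000": fm["fm1000"],
        "ignition_component": fm["ic"],
    })
    if "usable" in fm.coords:
        ds = ds.assign_coords(usable=fm["usable"])
    return ds


def classify_rxday(v: Mapping[str, float], env: PrescriptionEnvelope) -> bool:
    """True iff every variable bounded by the envelope lies inside its range.

    Bounds are inclusive.  A variable the envelope constrains but the
    evaluation vector lacks (or carries as NaN) raises rather than silently
    passing.
    """
    for var, (lo, hi) in env.bounds.items():
        if var not in v or v[var] is None:
            raise KeyError(f"evaluation vector lacks required variable {var!r}")
        x = float(v[var])
        if np.isnan(x):
            raise KeyError(f"evaluation vector has NaN for required variable {var!r}")
        if not (lo <= x <= hi):
            return False
    return True


def _envelope_mask(ev: xr.Dataset, env: PrescriptionEnvelope) -> xr.DataArray:
    """Vectorized conjunction of inclusive bound checks over the grid."""
    ok = xr.ones_like(ev["temp"], dtype=bool)
    for var, (lo, hi) in env.bounds.items():
        if var not in ev:
            raise KeyError(f"evaluation dataset lacks required variable {var!r}")
        ok = ok & (ev[var] >= lo) & (ev[var] <= hi)
    return ok


def rxday_grid(weather: xr.Dataset, fm: xr.Dataset, mask: xr.DataArray,
               env_forest: PrescriptionEnvelope,
               env_nonforest: PrescriptionEnvelope,
               variant: str = "veg_aware",
               env_all: PrescriptionEnvelope | None = None) -> xr.DataArray:
    """Boolean RxDay grid under the requested definition variant.

    veg_aware applies the forest envelope where the mask is forest and the
    non-forest envelope elsewhere; *_uniform variants apply one envelope
    everywhere; no_fuel_moisture drops every fuel-moisture and ignition
    bound (meteorology-only definition); no_heavy_fuel_moisture drops only
    the 100-h/1000-h bounds.  Days inside the fuel-moisture spin-up window
    are excluded from the result.
    """
    if variant not in RX_VARIANTS:
        raise ValueError(f"unknown RxDay variant {variant!r}; expected one of {RX_VARIANTS}")
    ev = daily_evaluation_vector(weather, fm)
    if "usable" in ev.coords:
        ev = ev.where(ev["usable"], drop=True).drop_vars("usable")

    ef, en = env_forest, env_nonforest
    if variant == "no_fuel_moisture":
        ef, en = ef.drop(FM_VARS), en.drop(FM_VARS)
    elif variant == "no_heavy_fuel_moisture":
        ef, en = ef.drop(HEAVY_FM_VARS), en.drop(HEAVY_FM_VARS)

    if variant == "forest_uniform":
        rx = _envelope_mask(ev, env_forest)
    elif variant == "nonforest_uniform":
        rx = _envelope_mask(ev, env_nonforest)
    elif variant == "allplans_uniform":
        if env_all is None:
            raise ValueError("allplans_uniform requires env_all")
        rx = _envelope_mask(ev, env_all)
    else:
        rx = xr.where(mask, _envelope_mask(ev, ef), _envelope_mask(ev, en))

    rx = rx.rename("rxday").astype(bool).transpose("time", "lat", "lon")
    rx.attrs["variant"] = variant
    return rx
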