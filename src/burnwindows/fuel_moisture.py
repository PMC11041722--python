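"""NFDRS dead fuel moisture and ignition component from daily weather.

Implements the classic (1978/1985) National Fire Danger Rating System
formulation: a three-regime equilibrium-moisture-content (EMC) polynomial in
relative humidity and dry-bulb temperature; a day-length-weighted daily EMC;
1-h and 10-h fine fuel moistures as fixed scalings of the weighted EMC; 100-h
and 1000-h moistures as first-order relaxations toward precipitation-adjusted
daily boundary values (the 1000-h class toward a trailing 7-day mean
boundary); and an ignition component derived from the probability-of-ignition
polynomial in fine fuel moisture and temperature.

Public interfaces use SI units (degC, m/s, mm); temperatures are converted to
Fahrenheit once at the module boundary, where the reference formulas live.
All NFDRS constants are centralized in ``NFDRS_CONSTANTS`` for auditability.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "NFDRS_CONSTANTS",
    "FmState",
    "equilibrium_moisture_content",
    "daylength_hours",
    "emc_bar",
    "precip_duration",
    "fm1",
    "fm10",
    "fm100_step",
    "fm1000_step",
    "ignition_component",
    "compute_fuel_moisture_grid",
    "celsius_to_fahrenheit",
]

NFDRS_CONSTANTS = {
    # EMC regimes (RH in %, T in degF, EMC in % of dry weight)
    "emc_lo": (0.03229, 0.281073, 0.000578),        # RH < 10
    "emc_mid": (2.22749, 0.160107, 0.014784),       # 10 <= RH <= 50
    "emc_hi": (21.0606, 0.005565, 0.00035, 0.483199),  # RH > 50
    # fine-fuel scalings of the day-length-weighted EMC
    "fm1_scale": 1.03,
    "fm10_scale": 1.28,
    # retained fractions of (boundary - previous) per daily step
    "fm100_fraction": 1.0 - 0.87 * np.exp(-0.24),
    "fm1000_fraction": 1.0 - 0.82 * np.exp(-0.168),
    # boundary-value precipitation terms: ((24-PDUR)*EMC + PDUR*(a*PDUR + b))/24
    "bndry100_rain": (0.5, 41.0),
    "bndry1000_rain": (2.7, 76.0),
    "bndry1000_window": 7,                           # trailing days averaged
    # precipitation-duration model: ceil(P/5) h capped at 8, zero below trace
    "pdur_mm_per_hour": 5.0,
    "pdur_cap_hours": 8.0,
    "trace_precip_mm": 0.25,
    # probability of ignition: heat-of-ignition polynomial and shape exponent
    "qign": (144.5, 0.266, 0.00058, 0.01, 18.54, 0.151, 6.4),
    "pign_norm": 0.000923 / 50.0,
    "pign_exponent": 3.66,
    "extinction_moisture": 33.0,                     # fm1 at/above which IC = 0
}


def celsius_to_fahrenheit(t_c):
    return np.asarray(t_c, float) * 9.0 / 5.0 + 32.0


def equilibrium_moisture_content(temp_f, rh):
    """EMC (%) from dry-bulb temperature (degF) and relative humidity (%).

    Three-regime polynomial; monotone increasing in RH within each regime
    over the physical range.
    """
    temp_f = np.asarray(temp_f, float)
    rh = np.asarray(rh, float)
    if bool(np.any((rh < 0) | (rh > 100))):
        raise ValueError("relative humidity must lie in [0, 100] %")
    a0, a1, a2 = NFDRS_CONSTANTS["emc_lo"]
    b0, b1, b2 = NFDRS_CONSTANTS["emc_mid"]
    c0, c1, c2, c3 = NFDRS_CONSTANTS["emc_hi"]
    emc = np.select(
        [rh < 10.0, rh <= 50.0],
        [a0 + a1 * rh - a2 * rh * temp_f,
         b0 + b1 * rh - b2 * temp_f],
        default=c0 + c1 * rh * rh - c2 * rh * temp_f - c3 * rh,
    )
    return np.maximum(emc, 0.0)


def daylength_hours(latitude, day_of_year):
    """Hours of daylight from the standard solar-declination geometry.

    Valid away from polar circles (|latitude| < 66.5 deg); the study domain
    spans roughly 31-49 degN.
    """
    latitude = np.asarray(latitude, float)
    if bool(np.any(np.abs(latitude) >= 66.5)):
        raise ValueError("daylength model is restricted to |latitude| < 66.5 deg")
    doy = np.asarray(day_of_year, float)
    decl = np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    lat = np.deg2rad(latitude)
    cos_ha = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_ha)


def emc_bar(emc_min, emc_max, daylight):
    """Day-length-weighted daily EMC.

    ``emc_min`` is the daytime EMC (at Tmax, RHmin) weighted by the
    daylight hours D; ``emc_max`` the nighttime EMC (at Tmin, RHmax)
    weighted by 24 - D.
    """
    daylight = np.asarray(daylight, float)
    if bool(np.any((daylight <= 0) | (daylight >= 24))):
        raise ValueError("daylight hours must lie strictly inside (0, 24)")
    return (daylight * np.asarray(emc_min, float)
            + (24.0 - daylight) * np.asarray(emc_max, float)) / 24.0


def precip_duration(precip_mm):
    """Hours of precipitation inferred from the daily amount.

    Daily grids carry amounts only, so duration is modelled as
    ceil(P / 5 mm) hours, capped at 8 h, and 0 below a 0.25 mm trace —
    monotone nondecreasing in the amount.
    """
    p = np.asarray(precip_mm, float)
    if bool(np.any(p < 0)):
        raise ValueError("precipitation must be nonnegative")
    rate = NFDRS_CONSTANTS["pdur_mm_per_hour"]
    cap = NFDRS_CONSTANTS["pdur_cap_hours"]
    hours = np.minimum(cap, np.ceil(p / rate))
    return np.where(p >= NFDRS_CONSTANTS["trace_precip_mm"], hours, 0.0)


def fm1(emc_bar_value):
    """1-h dead fuel moisture (%): fine fuels track the weighted EMC."""
    return NFDRS_CONSTANTS["fm1_scale"] * np.asarray(emc_bar_value, float)


def fm10(emc_bar_value):
    """10-h dead fuel moisture (%)."""
    return NFDRS_CONSTANTS["fm10_scale"] * np.asarray(emc_bar_value, float)


def _boundary(emc_bar_value, pdur, rain_coeffs):
    a, b = rain_coeffs
    pdur = np.asarray(pdur, float)
    return ((24.0 - pdur) * np.asarray(emc_bar_value, float)
            + pdur * (a * pdur + b)) / 24.0


def boundary100(emc_bar_value, pdur):
    """Daily 100-h boundary value (%), wet hours pulled toward saturation."""
    return _boundary(emc_bar_value, pdur, NFDRS_CONSTANTS["bndry100_rain"])


def boundary1000(emc_bar_value, pdur):
    """Daily 1000-h boundary value (%)."""
    return _boundary(emc_bar_value, pdur, NFDRS_CONSTANTS["bndry1000_rain"])


def fm100_step(prev, boundary):
    """One daily relaxation of the 100-h moisture toward its boundary."""
    f = NFDRS_CONSTANTS["fm100_fraction"]
    return np.asarray(prev, float) + (np.asarray(boundary, float) - prev) * f


def fm1000_step(prev, boundary_7day_mean):
    """One daily relaxation of the 1000-h moisture toward the 7-day mean boundary."""
    f = NFDRS_CONSTANTS["fm1000_fraction"]
    return np.asarray(prev, float) + (np.asarray(boundary_7day_mean, float) - prev) * f


def ignition_component(fm1_value, temp_f):
    """Ignition component (0-100) from fine fuel moisture and temperature.

    Uses the heat-of-ignition polynomial QIGN(T, m) and the resulting
    probability of ignition ((344 - QIGN)/10)^3.66 scaled to percent; fuels
    at or beyond the extinction moisture cannot ignite.  Monotone
    nonincreasing in fm1 and nondecreasing in temperature.
    """
    m = np.asarray(fm1_value, float)
    t = np.asarray(temp_f, float)
    if bool(np.any(m < 0)):
        raise ValueError("fuel moisture must be nonnegative")
    q0, q1, q2, q3, q4, q5, q6 = NFDRS_CONSTANTS["qign"]
    qign = (q0 - q1 * t - q2 * t * t - q3 * t * m
            + q4 * (1.0 - np.exp(-q5 * m)) + q6 * m)
    chi = np.maximum((344.0 - qign) / 10.0, 0.0)
    p_ign = 100.0 * NFDRS_CONSTANTS["pign_norm"] * chi ** NFDRS_CONSTANTS["pign_exponent"]
    p_ign = np.clip(p_ign, 0.0, 100.0)
    return np.where(m >= NFDRS_CONSTANTS["extinction_moisture"], 0.0, p_ign)


@dataclass
class FmState:
    """Recursion state for the slow (100-h / 1000-h) fuel moisture classes."""

    fm100: float
    fm1000: float
    boundary_buffer: deque = field(default_factory=lambda: deque(maxlen=7))

    def step(self, emc_bar_value: float, pdur_hours: float) -> tuple[float, float]:
        """Advance one day; returns the updated (fm100, fm1000)."""
        b100 = float(boundary100(emc_bar_value, pdur_hours))
        b1000 = float(boundary1000(emc_bar_value, pdur_hours))
        self.boundary_buffer.append(b1000)
        self.fm100 = float(fm100_step(self.fm100, b100))
        self.fm1000 = float(fm1000_step(self.fm1000, float(np.mean(self.boundary_buffer))))
        return self.fm100, self.fm1000


def compute_fuel_moisture_grid(weather: xr.Dataset, spinup: int = 90) -> xr.Dataset:
    """All NFDRS fields for every cell-day of a daily weather grid.

    The slow classes are initialized from their own first boundary values
    (the 1000-h class from the mean of the first up-to-7 daily boundaries)
    and the first ``spinup`` days are flagged unusable via the boolean
    ``usable`` time coordinate; 90 days comfortably exceeds the 1000-h
    relaxation memory.  Purely local in space: each cell evolves as the
    scalar recursions would.
    """
    nt = weather.sizes["time"]
    if nt <= spinup:
        raise ValueError(f"need more than spinup={spinup} days, got {nt}")

    tmax_f = celsius_to_fahrenheit(weather["tmax"].values)
    tmin_f = celsius_to_fahrenheit(weather["tmin"].values)
    rhmin = weather["rhmin"].values
    rhmax = weather["rhmax"].values
    precip = weather["precip"].values

    emc_min = equilibrium_moisture_content(tmax_f, rhmin)
    emc_max = equilibrium_moisture_content(tmin_f, rhmax)

    time = pd.DatetimeIndex(weather["time"].values)
    doy = time.dayofyear.to_numpy(float)
    lat = weather["lat"].values
    daylight = daylength_hours(lat[None, :, None], doy[:, None, None])
    daylight = np.broadcast_to(daylight, emc_min.shape)

    emcbar = emc_bar(emc_min, emc_max, daylight)
    pdur = precip_duration(precip)
    b100 = boundary100(emcbar, pdur)
    b1000 = boundary1000(emcbar, pdur)

    nwin = NFDRS_CONSTANTS["bndry1000_window"]
    fm100_arr = np.empty_like(b100)
    fm1000_arr = np.empty_like(b1000)
    fm100_arr[0] = b100[0]
    fm1000_arr[0] = b1000[: min(nwin, nt)].mean(axis=0)
    for t in range(1, nt):
        fm100_arr[t] = fm100_step(fm100_arr[t - 1], b100[t])
        bbar = b1000[max(0, t - nwin + 1): t + 1].mean(axis=0)
        fm1000_arr[t] = fm1000_step(fm1000_arr[t - 1], bbar)

    fm1_arr = fm1(emcbar)
    ic = ignition_component(fm1_arr, tmax_f)

    dims = ("time", "lat", "lon")
    coords = {k: weather[k] for k in dims}
    usable = np.arange(nt) >= spinup
    ds = xr.Dataset(
        {
            "emc_min": (dims, emc_min, {"units": "%"}),
            "emc_max": (dims, emc_max, {"units": "%"}),
            "emc_bar": (dims, emcbar, {"units": "%"}),
            "fm1": (dims, fm1_arr, {"units": "%"}),
            "fm10": (dims, fm10(emcbar), {"units": "%"}),
            "fm100": (dims, fm100_arr, {"units": "%"}),
            "fm1000": (dims, fm1000_arr, {"units": "%"}),
            "ic": (dims, ic, {"units": "1", "long_name": "ignition component"}),
        },
        coords={**coords, "usable": ("time", usable)},
        attrs={"spinup_days": spinup},
    )
    return ds
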