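"""Stochastic generation of gridded daily surface weather and related fixtures.

This module emulates the statistical structure of 4-km daily meteorological
grids (observational analyses and statistically downscaled climate-model
ensembles) well enough to exercise the full burn-window pipeline without any
external data: seasonal cycles, secular trends, lag-1 autocorrelated
anomalies with hot/dry coupling, Bernoulli–gamma wet-day precipitation, a
smooth latitudinal gradient with spatially coherent noise, plus vegetation
masks, burn-plan sets, and pseudo-model ensembles with per-member biases.

All randomness flows from a single integer seed; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .prescriptions import VEG_FOREST, VEG_NONFOREST, BurnPlan

__all__ = [
    "VariableClimatology",
    "SyntheticClimateSpec",
    "EnsembleSpec",
    "generate_weather_grid",
    "generate_vegetation_mask",
    "generate_burn_plans",
    "generate_ensemble",
    "validate_weather",
]

WEATHER_VARS = ("tmax", "tmin", "rhmax", "rhmin", "wind10", "precip")

#: days per tropical year used for harmonic phases and trend scaling
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class VariableClimatology:
    """Seasonal-cycle + trend description of one surface variable.

    mean
        annual-mean value at the domain's central latitude.
    amplitude
        half peak-to-trough seasonal range; the cycle is a single cosine
        harmonic peaking at `phase_doy`.
    phase_doy
        day of year of the seasonal maximum.
    trend_per_decade
        linear secular trend, units per decade, applied from the first day.
    anomaly_std
        standard deviation of daily AR(1) anomalies.
    lat_gradient
        units per degree latitude (northward).
    """

    mean: float
    amplitude: float = 0.0
    phase_doy: float = 200.0
    trend_per_decade: float = 0.0
    anomaly_std: float = 0.0
    lat_gradient: float = 0.0


def _default_tmax() -> VariableClimatology:
    return VariableClimatology(mean=18.0, amplitude=12.0, phase_doy=200.0,
                               anomaly_std=3.0, lat_gradient=-0.7)


def _default_rhmin() -> VariableClimatology:
    return VariableClimatology(mean=32.0, amplitude=-14.0, phase_doy=200.0,
                               anomaly_std=10.0, lat_gradient=1.0)


def _default_wind() -> VariableClimatology:
    return VariableClimatology(mean=3.0, amplitude=0.6, phase_doy=100.0,
                               anomaly_std=1.2)


def _default_wet_day_prob() -> dict[str, float]:
    # winter-wet Mediterranean-type regime typical of the study domain
    return {"DJF": 0.40, "MAM": 0.28, "JJA": 0.10, "SON": 0.25}


@dataclass(frozen=True)
class SyntheticClimateSpec:
    """Full description of a synthetic daily-weather process on a lat/lon grid."""

    n_lat: int = 10
    n_lon: int = 10
    lat_bounds: tuple[float, float] = (31.3, 48.9)
    lon_bounds: tuple[float, float] = (235.3, 256.9)
    start: str = "1981-01-01"
    end: str = "2020-12-31"
    tmax: VariableClimatology = field(default_factory=_default_tmax)
    rhmin: VariableClimatology = field(default_factory=_default_rhmin)
    wind: VariableClimatology = field(default_factory=_default_wind)
    diurnal_range: float = 14.0          # tmax - tmin, degC (kept > 0)
    rh_span: float = 35.0                # rhmax - rhmin before clipping, %
    ar1: float = 0.7                     # lag-1 anomaly autocorrelation
    t_rh_coupling: float = -0.6          # corr(T anomaly, RH anomaly)
    spatial_smoothing: float = 1.5       # gaussian sigma, grid cells
    wet_day_prob: dict[str, float] = field(default_factory=_default_wet_day_prob)
    precip_shape: float = 0.7            # gamma shape of wet-day amounts
    precip_scale: float = 8.0            # gamma scale, mm
    seed: int = 0

    def validate(self) -> None:
        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise ValueError(f"end {self.end!r} must fall after start {self.start!r}")
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must have at least one cell per axis")
        for name in ("tmax", "rhmin", "wind"):
            clim: VariableClimatology = getattr(self, name)
            if clim.anomaly_std < 0:
                raise ValueError(f"{name}.anomaly_std must be >= 0, got {clim.anomaly_std}")
        lo = self.rhmin.mean - abs(self.rhmin.amplitude)
        hi = self.rhmin.mean + abs(self.rhmin.amplitude)
        if lo < 0.0 or hi > 100.0:
            raise ValueError("rhmin climatology must stay within [0, 100]")
        if self.diurnal_range <= 0:
            raise ValueError("diurnal_range must be positive so tmax > tmin")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 must lie in [0, 1)")
        if not -1.0 <= self.t_rh_coupling <= 1.0:
            raise ValueError("t_rh_coupling must lie in [-1, 1]")
        for season, p in self.wet_day_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"wet_day_prob[{season!r}] must lie in [0, 1]")
        if self.precip_shape <= 0 or self.precip_scale < 0:
            raise ValueError("gamma precipitation parameters must be positive")


@dataclass(frozen=True)
class EnsembleSpec:
    """Pseudo-model ensemble: per-member additive biases and trend perturbations.

    ``biases[i]`` / ``trend_perturbations[i]`` map variable name
    (tmax / rhmin / wind) to an additive offset on the climatological mean,
    respectively on the per-decade trend.  Member seeds default to
    ``base_seed + i`` so a single zero-bias member reproduces the base grid.
    """

    n_members: int = 18
    biases: tuple[dict[str, float], ...] = ()
    trend_perturbations: tuple[dict[str, float], ...] = ()
    member_seeds: tuple[int, ...] = ()

    def validate(self) -> None:
        if self.n_members < 1:
            raise ValueError("ensemble needs at least one member")
        for name in ("biases", "trend_perturbations", "member_seeds"):
            seq = getattr(self, name)
            if seq and len(seq) != self.n_members:
                raise ValueError(f"{name} must have one entry per member")


# ---------------------------------------------------------------------------
# weather process


def _season_of_month(month: np.ndarray) -> np.ndarray:
    """Map month number to season label index 0..3 = DJF,MAM,JJA,SON."""
    return (month % 12) // 3


def _harmonic(doy: np.ndarray, clim: VariableClimatology) -> np.ndarray:
    return clim.mean + clim.amplitude * np.cos(
        2.0 * np.pi * (doy - clim.phase_doy) / DAYS_PER_YEAR
    )


def _ar1_field(rng: np.random.Generator, n_time: int, n_lat: int, n_lon: int,
               phi: float, smooth: float) -> np.ndarray:
    """Standardized AR(1)-in-time field with spatially coherent innovations."""
    eps = rng.standard_normal((n_time, n_lat, n_lon))
    if smooth > 0 and (n_lat > 1 or n_lon > 1):
        eps = ndimage.gaussian_filter(eps, sigma=(0.0, smooth, smooth), mode="nearest")
        sd = eps.std()
        if sd > 0:
            eps /= sd
    out = np.empty_like(eps)
    out[0] = eps[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n_time):
        out[t] = phi * out[t - 1] + scale * eps[t]
    return out


def generate_weather_grid(spec: SyntheticClimateSpec) -> xr.Dataset:
    """Simulate a daily weather grid: climatology + trend + AR(1) anomalies.

    Returns an :class:`xarray.Dataset` with variables tmax/tmin (degC),
    rhmax/rhmin (%), wind10 (m/s) and precip (mm/day) on (time, lat, lon),
    satisfying all physical invariants (tmax >= tmin, 0 <= rhmin <= rhmax
    <= 100, wind10 >= 0, precip >= 0) on every grid-day.
    """
    spec.validate()
    time = pd.date_range(spec.start, spec.end, freq="D")
    lat = np.linspace(spec.lat_bounds[0], spec.lat_bounds[1], spec.n_lat)
    lon = np.linspace(spec.lon_bounds[0], spec.lon_bounds[1], spec.n_lon)
    nt, ny, nx = len(time), spec.n_lat, spec.n_lon

    doy = time.dayofyear.to_numpy(float)[:, None, None]
    years_elapsed = ((time - time[0]).days.to_numpy(float) / DAYS_PER_YEAR)[:, None, None]
    dlat = (lat - lat.mean())[None, :, None]

    seeds = {name: np.random.default_rng([spec.seed, k])
             for k, name in enumerate(("temp", "rh", "wind", "wet", "amount"))}

    a_t = _ar1_field(seeds["temp"], nt, ny, nx, spec.ar1, spec.spatial_smoothing)
    a_rh_ind = _ar1_field(seeds["rh"], nt, ny, nx, spec.ar1, spec.spatial_smoothing)
    a_w = _ar1_field(seeds["wind"], nt, ny, nx, spec.ar1, spec.spatial_smoothing)
    c = spec.t_rh_coupling
    a_rh = c * a_t + np.sqrt(1.0 - c * c) * a_rh_ind

    def _field(clim: VariableClimatology, anom: np.ndarray) -> np.ndarray:
        base = _harmonic(doy, clim) + clim.lat_gradient * dlat
        base = base + clim.trend_per_decade * years_elapsed / 10.0
        return base + clim.anomaly_std * anom

    tmax = _field(spec.tmax, a_t)
    tmin = tmax - spec.diurnal_range
    rhmin = np.clip(_field(spec.rhmin, a_rh), 0.0, 100.0)
    rhmax = np.clip(rhmin + spec.rh_span, 0.0, 100.0)
    wind10 = np.clip(_field(spec.wind, a_w), 0.0, None)

    season_idx = _season_of_month(time.month.to_numpy())
    p_by_season = np.array([spec.wet_day_prob.get(s, 0.0)
                            for s in ("DJF", "MAM", "JJA", "SON")])
    p_wet = p_by_season[season_idx][:, None, None]
    wet = seeds["wet"].random((nt, ny, nx)) < p_wet
    amounts = seeds["amount"].gamma(spec.precip_shape, spec.precip_scale, (nt, ny, nx))
    precip = np.where(wet, amounts, 0.0)

    ds = xr.Dataset(
        {
            "tmax": (("time", "lat", "lon"), tmax, {"units": "degC"}),
            "tmin": (("time", "lat", "lon"), tmin, {"units": "degC"}),
            "rhmax": (("time", "lat", "lon"), rhmax, {"units": "%"}),
            "rhmin": (("time", "lat", "lon"), rhmin, {"units": "%"}),
            "wind10": (("time", "lat", "lon"), wind10, {"units": "m s-1"}),
            "precip": (("time", "lat", "lon"), precip, {"units": "mm"}),
        },
        coords={"time": time, "lat": ("lat", lat, {"units": "degrees_north"}),
                "lon": ("lon", lon, {"units": "degrees_east"})},
        attrs={"Conventions": "CF-1.8", "source": "burnwindows synthetic generator",
               "seed": spec.seed},
    )
    return ds


def validate_weather(ds: xr.Dataset) -> None:
    """Raise ValueError if a weather dataset violates its physical invariants."""
    for name in WEATHER_VARS:
        if name not in ds:
            raise ValueError(f"weather dataset is missing variable {name!r}")
    for axis in ("time", "lat", "lon"):
        vals = ds[axis].values
        d = np.diff(vals)
        if len(vals) > 1 and not bool(np.all(d > d.dtype.type(0))):
            raise ValueError(f"axis {axis!r} must be strictly increasing")
    checks = {
        "tmax >= tmin": (ds.tmax >= ds.tmin).all(),
        "rhmin <= rhmax": (ds.rhmin <= ds.rhmax).all(),
        "rh within [0, 100]": ((ds.rhmin >= 0) & (ds.rhmax <= 100)).all(),
        "wind10 >= 0": (ds.wind10 >= 0).all(),
        "precip >= 0": (ds.precip >= 0).all(),
    }
    for label, ok in checks.items():
        if not bool(ok):
            raise ValueError(f"weather dataset violates invariant: {label}")


# ---------------------------------------------------------------------------
# vegetation mask


def generate_vegetation_mask(lat: np.ndarray, lon: np.ndarray,
                             forest_fraction: float, seed: int,
                             smoothing: float = 2.0) -> xr.DataArray:
    """Spatially coherent forest / non-forest mask.

    A Gaussian-smoothed white-noise field is thresholded at the empirical
    quantile matching ``forest_fraction``, so the realized forest share
    equals the request up to grid discretization while neighbouring cells
    stay correlated (stand-in for an ecological site-potential raster).
    Returns a boolean DataArray (True = forest).
    """
    if not 0.0 <= forest_fraction <= 1.0:
        raise ValueError(f"forest_fraction must lie in [0, 1], got {forest_fraction}")
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    rng = np.random.default_rng([seed, 97])
    fieldv = rng.standard_normal((lat.size, lon.size))
    if smoothing > 0 and fieldv.size > 1:
        fieldv = ndimage.gaussian_filter(fieldv, sigma=smoothing, mode="nearest")
    if forest_fraction >= 1.0:
        mask = np.ones_like(fieldv, bool)
    elif forest_fraction <= 0.0:
        mask = np.zeros_like(fieldv, bool)
    else:
        thresh = np.quantile(fieldv, 1.0 - forest_fraction)
        mask = fieldv > thresh
        # quantile ties can under-fill; top up deterministically by field value
        deficit = int(round(forest_fraction * fieldv.size)) - int(mask.sum())
        if deficit > 0:
            order = np.argsort(fieldv, axis=None)[::-1]
            extra = [i for i in order if not mask.flat[i]][:deficit]
            mask.flat[extra] = True
    return xr.DataArray(mask, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"),
                        name="forest", attrs={"long_name": "forest/woodland mask"})


# ---------------------------------------------------------------------------
# burn plans

# (lower, upper, plan-to-plan jitter half-width) per variable, SI units.
_FOREST_PLAN_TEMPLATE = {
    "temp": (1.5, 29.5, 2.0),
    "rh": (22.0, 55.0, 4.0),
    "midflame_wind": (0.4, 3.6, 0.3),
    "fm1": (5.0, 12.0, 1.0),
    "fm10": (6.0, 15.0, 1.5),
    "fm100": (8.0, 20.0, 2.0),
    "fm1000": (10.0, 25.0, 2.5),
    "ignition_component": (10.0, 60.0, 5.0),
}
_NONFOREST_PLAN_TEMPLATE = {
    "temp": (0.0, 32.0, 2.0),
    "rh": (18.0, 50.0, 4.0),
    "midflame_wind": (0.4, 4.0, 0.3),
    "fm1": (4.0, 10.0, 1.0),
    "fm10": (5.0, 13.0, 1.5),
    "ignition_component": (15.0, 70.0, 5.0),
}


def generate_burn_plans(n_forest: int, n_nonforest: int, seed: int) -> list[BurnPlan]:
    """Synthetic burn-plan set emulating a small archive of real plans.

    Every plan carries temperature, relative-humidity, mid-flame wind,
    fine-fuel moisture (1-h/10-h) and ignition-component envelopes; forest
    plans additionally constrain 100-h and 1000-h fuel moisture while
    non-forest plans never do.  Bounds are the class template jittered per
    plan, with lower < upper guaranteed by construction.
    """
    if n_forest < 1 or n_nonforest < 1:
        raise ValueError("need at least one plan of each vegetation class")
    rng = np.random.default_rng([seed, 11])
    plans: list[BurnPlan] = []
    for veg, template, count in ((VEG_FOREST, _FOREST_PLAN_TEMPLATE, n_forest),
                                 (VEG_NONFOREST, _NONFOREST_PLAN_TEMPLATE, n_nonforest)):
        for i in range(count):
            bounds = {}
            for var, (lo, hi, jitter) in template.items():
                lo_i = lo + rng.uniform(-jitter, jitter)
                hi_i = hi + rng.uniform(-jitter, jitter)
                if var in ("rh", "fm1", "fm10", "fm100", "fm1000"):
                    lo_i = max(lo_i, 0.0)
                bounds[var] = (round(lo_i, 2), round(hi_i, 2))
            plans.append(BurnPlan(identifier=f"{veg}-{i:02d}", veg_class=veg,
                                  bounds=bounds))
    return plans


# ---------------------------------------------------------------------------
# pseudo-model ensemble


def symmetric_ensemble_spec(n_members: int, tmax_bias: float = 1.5,
                            rhmin_bias: float = 5.0,
                            trend_spread: float = 0.15) -> EnsembleSpec:
    """Ensemble with biases spread symmetrically about zero.

    Members take evenly spaced additive biases in ±tmax_bias (degC) and
    ∓rhmin_bias (%, anti-phased with temperature), and per-decade trend
    perturbations of ±trend_spread times the member's normalized rank, so
    the ensemble-mean bias vanishes by construction.
    """
    if n_members == 1:
        ranks = np.array([0.0])
    else:
        ranks = np.linspace(-1.0, 1.0, n_members)
    biases = tuple({"tmax": float(tmax_bias * r), "rhmin": float(-rhmin_bias * r)}
                   for r in ranks)
    trends = tuple({"tmax": float(trend_spread * r), "rhmin": float(-trend_spread * 3 * r)}
                   for r in ranks)
    return EnsembleSpec(n_members=n_members, biases=biases, trend_perturbations=trends)


def _perturbed_clim(clim: VariableClimatology, bias: float,
                    trend_delta: float) -> VariableClimatology:
    return replace(clim, mean=clim.mean + bias,
                   trend_per_decade=clim.trend_per_decade + trend_delta)


def generate_ensemble(spec: SyntheticClimateSpec, ens: EnsembleSpec) -> list[xr.Dataset]:
    """One weather grid per pseudo-model member.

    Member i is the base process with member-i additive biases / trend
    perturbations applied to the climatology and its own seed stream
    (default ``spec.seed + i``).
    """
    spec.validate()
    ens.validate()
    members = []
    for i in range(ens.n_members):
        bias = ens.biases[i] if ens.biases else {}
        tpert = ens.trend_perturbations[i] if ens.trend_perturbations else {}
        mseed = ens.member_seeds[i] if ens.member_seeds else spec.seed + i
        mspec = replace(
            spec,
            tmax=_perturbed_clim(spec.tmax, bias.get("tmax", 0.0), tpert.get("tmax", 0.0)),
            rhmin=_perturbed_clim(spec.rhmin, bias.get("rhmin", 0.0), tpert.get("rhmin", 0.0)),
            wind=_perturbed_clim(spec.wind, bias.get("wind", 0.0), tpert.get("wind", 0.0)),
            seed=mseed,
        )
        grid = generate_weather_grid(mspec)
        grid.attrs["member"] = i
        members.append(grid)
    return members
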