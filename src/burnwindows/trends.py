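"""Seasonal aggregation, regional averaging, and trend statistics.

Turns boolean day grids into seasonal/annual count series, collapses them to
cosine-latitude-weighted regional means over land, and characterizes change:
ordinary-least-squares linear trends with two-tailed significance, the
accumulated change over a fit period, percent change against a baseline,
centered running means, epoch differences, interannual variability, and
ensemble-member agreement on the sign/magnitude of change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

__all__ = [
    "RegionBox",
    "TrendResult",
    "WUS_DOMAIN",
    "PACIFIC_SOUTHWEST",
    "NORTHERN_TIER",
    "FOUR_CORNERS",
    "SUBREGIONS",
    "SEASON_MONTHS",
    "seasonal_counts",
    "regional_mean",
    "linear_trend",
    "running_mean",
    "epoch_difference",
    "ensemble_statistics",
    "interannual_sd",
]


@dataclass(frozen=True)
class RegionBox:
    """Named latitude/longitude box (degrees N, degrees E on 0-360)."""

    name: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError(f"region {self.name!r}: min must be below max on both axes")


# Study domain and sub-regions (western United States).
WUS_DOMAIN = RegionBox("WUS", 31.3, 48.9, 235.3, 256.9)
PACIFIC_SOUTHWEST = RegionBox("Pacific Southwest", 32.0, 42.0, 235.3, 246.0)
NORTHERN_TIER = RegionBox("Northern Tier", 42.0, 48.9, 235.3, 256.9)
FOUR_CORNERS = RegionBox("Four Corners", 31.3, 42.0, 246.0, 256.0)
SUBREGIONS = (PACIFIC_SOUTHWEST, NORTHERN_TIER, FOUR_CORNERS)

SEASON_MONTHS = {
    "DJF": (12, 1, 2),
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
    "annual": tuple(range(1, 13)),
}


@dataclass(frozen=True)
class TrendResult:
    """OLS linear trend of a yearly series.

    slope is in series units per year; accumulated = slope * (n - 1) spans
    the fit period; percent is accumulated relative to the baseline
    (fitted value at the first year, or the period mean); p_value is the
    two-tailed significance of the slope.
    """

    slope: float
    accumulated: float
    percent: float
    p_value: float
    n_years: int
    baseline: float


def _season_year_bounds(season: str, year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """First and last calendar day of a labeled season-year."""
    if season == "DJF":
        start = pd.Timestamp(year=year - 1, month=12, day=1)
        end = pd.Timestamp(year=year, month=3, day=1) - pd.Timedelta(days=1)
    elif season == "annual":
        start = pd.Timestamp(year=year, month=1, day=1)
        end = pd.Timestamp(year=year, month=12, day=31)
    else:
        m0, _, m2 = SEASON_MONTHS[season]
        start = pd.Timestamp(year=year, month=m0, day=1)
        last = pd.Timestamp(year=year, month=m2, day=1) + pd.offsets.MonthEnd(0)
        end = last
    return start, end


def seasonal_counts(days: xr.DataArray, season: str = "annual") -> xr.DataArray:
    """Count True days per season-year (or calendar year) per cell.

    December is attached to the *following* year's DJF label; season-years
    not fully covered by the time axis (the leading December-less DJF, and
    any trailing partial season) are dropped so every retained count spans a
    complete season.
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"unknown season {season!r}; expected one of {sorted(SEASON_MONTHS)}")
    time = pd.DatetimeIndex(np.asarray(days["time"].values))
    if len(time) == 0:
        raise ValueError("empty time range")
    months = time.month
    in_season = np.isin(months, SEASON_MONTHS[season])
    label_year = time.year + ((months == 12) & (season == "DJF")).astype(int)

    sel = xr.DataArray(in_season, dims="time", coords={"time": days["time"]})
    labels = xr.DataArray(label_year, dims="time", coords={"time": days["time"]},
                          name="year")
    subset = days.where(sel, other=False)
    counts = subset.astype("int64").groupby(labels).sum("time")

    complete = []
    for year in counts["year"].values:
        start, end = _season_year_bounds(season, int(year))
        if time[0] <= start and end <= time[-1]:
            complete.append(year)
    if not complete:
        raise ValueError(f"no complete {season} season in the time range")
    out = counts.sel(year=complete)
    out.attrs["season"] = season
    return out


def regional_mean(count_grid: xr.DataArray, region: RegionBox,
                  land_mask: xr.DataArray | None = None,
                  lat_weighted: bool = True) -> xr.DataArray:
    """Areal average over land cells inside a region box.

    Weights are cos(latitude) by default (grid cells shrink poleward);
    ``land_mask`` True marks land — ocean cells are excluded from the
    average.  Errors if the box contains no contributing cell.
    """
    lat = count_grid["lat"]
    lon = count_grid["lon"] % 360.0
    inside = ((lat >= region.lat_min) & (lat <= region.lat_max)
              & (lon >= region.lon_min) & (lon <= region.lon_max))
    weights = np.cos(np.deg2rad(lat)) if lat_weighted else xr.ones_like(lat, dtype=float)
    weights = weights * xr.ones_like(lon, dtype=float)  # broadcast to (lat, lon)
    weights = weights.where(inside, 0.0)
    if land_mask is not None:
        weights = weights.where(land_mask, 0.0)
    total = float(weights.sum())
    if total <= 0:
        raise ValueError(f"region {region.name!r} contains no contributing grid cell")
    return (count_grid * weights).sum(("lat", "lon")) / total


def linear_trend(series, baseline_mode: str = "fit_start") -> TrendResult:
    """OLS trend of a yearly series with two-tailed slope significance.

    ``baseline_mode`` selects the denominator of the percent change: the
    fitted value at the first year ("fit_start", default) or the period
    mean ("mean").
    """
    if isinstance(series, xr.DataArray):
        years = np.asarray(series["year"].values, float)
        values = np.asarray(series.values, float)
    elif isinstance(series, pd.Series):
        years = np.asarray(series.index, float)
        values = series.to_numpy(float)
    else:
        values = np.asarray(series, float)
        years = np.arange(len(values), dtype=float)
    if values.ndim != 1:
        raise ValueError("linear_trend expects a one-dimensional yearly series")
    n = len(values)
    if n < 3:
        raise ValueError("need at least three years to fit a trend")
    if np.ptp(years) == 0:
        raise ValueError("time axis is constant")
    fit = stats.linregress(years, values)
    accumulated = fit.slope * (years[-1] - years[0])
    if baseline_mode == "fit_start":
        baseline = fit.intercept + fit.slope * years[0]
    elif baseline_mode == "mean":
        baseline = float(np.mean(values))
    else:
        raise ValueError("baseline_mode must be 'fit_start' or 'mean'")
    percent = 100.0 * accumulated / baseline if baseline != 0 else np.nan
    return TrendResult(slope=float(fit.slope), accumulated=float(accumulated),
                       percent=float(percent), p_value=float(fit.pvalue),
                       n_years=n, baseline=float(baseline))


def running_mean(series, window: int = 5):
    """Centered moving average; endpoint windows shrink to the available span."""
    if window < 1:
        raise ValueError("window must be at least 1")
    if isinstance(series, xr.DataArray):
        dim = series.dims[-1]
        return series.rolling({dim: window}, center=True, min_periods=1).mean()
    s = pd.Series(np.asarray(series, float))
    out = s.rolling(window, center=True, min_periods=1).mean()
    if isinstance(series, pd.Series):
        return pd.Series(out.to_numpy(), index=series.index)
    return out.to_numpy()


def epoch_difference(count_grid: xr.DataArray, epoch_a: tuple[int, int],
                     epoch_b: tuple[int, int]) -> xr.DataArray:
    """Per-cell mean count in epoch_b minus mean count in epoch_a (inclusive years)."""
    years = count_grid["year"].values
    for lo, hi in (epoch_a, epoch_b):
        if lo > hi or lo < years.min() or hi > years.max():
            raise ValueError(f"epoch ({lo}, {hi}) must lie within the year range")
    if epoch_a[1] >= epoch_b[0] and epoch_b[1] >= epoch_a[0]:
        warnings.warn("epochs overlap", stacklevel=2)
    mean_a = count_grid.sel(year=slice(epoch_a[0], epoch_a[1])).mean("year")
    mean_b = count_grid.sel(year=slice(epoch_b[0], epoch_b[1])).mean("year")
    return mean_b - mean_a


def ensemble_statistics(member_series: Sequence, threshold: float,
                        direction: str = "decrease") -> dict:
    """Ensemble-mean yearly series and member agreement on accumulated change.

    Agreement counts members whose own OLS accumulated change is a decrease
    of at least ``threshold`` (direction="decrease") or an increase of at
    least ``threshold`` ("increase").
    """
    if len(member_series) < 1:
        raise ValueError("need at least one ensemble member")
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    arrays = []
    years_ref = None
    for s in member_series:
        if isinstance(s, xr.DataArray):
            yrs, vals = np.asarray(s["year"].values), np.asarray(s.values, float)
        elif isinstance(s, pd.Series):
            yrs, vals = np.asarray(s.index), s.to_numpy(float)
        else:
            vals = np.asarray(s, float)
            yrs = np.arange(len(vals))
        if years_ref is None:
            years_ref = yrs
        elif len(yrs) != len(years_ref) or not np.array_equal(yrs, years_ref):
            raise ValueError("ensemble members must share one year axis")
        arrays.append(vals)
    stacked = np.vstack(arrays)
    mean_series = pd.Series(stacked.mean(axis=0), index=years_ref)
    changes = [linear_trend(pd.Series(v, index=years_ref)).accumulated for v in arrays]
    thr = abs(threshold)
    if direction == "decrease":
        agree = sum(c <= -thr for c in changes)
    else:
        agree = sum(c >= thr for c in changes)
    return {"mean_series": mean_series, "accumulated_changes": changes,
            "n_agree": int(agree), "n_members": len(arrays)}


def interannual_sd(annual_counts: xr.DataArray) -> xr.DataArray:
    """Sample standard deviation (ddof=1) of annual counts per cell."""
    if annual_counts.sizes.get("year", 0) < 2:
        raise ValueError("need at least two years")
    return annual_counts.std("year", ddof=1)
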