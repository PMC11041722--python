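"""Low-level air-stagnation (LLS) days: weak surface wind and negligible rain.

A daily proxy for poor smoke ventilation: a grid-day is stagnant when the
daily-mean 10 m wind is below 3.2 m/s and daily accumulated precipitation is
below 1 mm (strict inequalities).  The classic air-stagnation index adds a
mid-tropospheric wind criterion; only the two near-surface criteria are kept
here, as surface ventilation and hydrometeor scavenging dominate the public
health relevance of prescribed-burn smoke.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from . import trends

__all__ = ["WIND_THRESHOLD_MS", "PRECIP_THRESHOLD_MM", "classify_lls", "lls_counts"]

WIND_THRESHOLD_MS = 3.2
PRECIP_THRESHOLD_MM = 1.0


def classify_lls(wind10_mean, precip, wind_thresh: float = WIND_THRESHOLD_MS,
                 precip_thresh: float = PRECIP_THRESHOLD_MM):
    """True where wind10 < wind threshold AND precip < precip threshold."""
    wind_arr = np.asarray(wind10_mean) if not isinstance(wind10_mean, xr.DataArray) else wind10_mean
    precip_arr = np.asarray(precip) if not isinstance(precip, xr.DataArray) else precip
    if bool(np.any(np.asarray(wind_arr) < 0)) or bool(np.any(np.asarray(precip_arr) < 0)):
        raise ValueError("wind and precipitation must be nonnegative")
    if wind_thresh < 0 or precip_thresh < 0:
        raise ValueError("thresholds must be nonnegative")
    return (wind_arr < wind_thresh) & (precip_arr < precip_thresh)


def lls_counts(weather: xr.Dataset, wind_thresh: float = WIND_THRESHOLD_MS,
               precip_thresh: float = PRECIP_THRESHOLD_MM,
               seasons: tuple[str, ...] = ("annual", "DJF", "MAM", "JJA", "SON"),
               ) -> dict[str, xr.DataArray]:
    """Per-cell seasonal and annual LLS-day counts.

    Returns one (year, lat, lon) count grid per requested season label,
    using the same complete-season calendar conventions as RxDay counting.
    """
    days = classify_lls(weather["wind10"], weather["precip"],
                        wind_thresh, precip_thresh)
    days = days.rename("lls")
    days.attrs.update(wind_threshold_ms=wind_thresh, precip_threshold_mm=precip_thresh)
    return {season: trends.seasonal_counts(days, season) for season in seasons}
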