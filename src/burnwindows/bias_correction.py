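"""Empirical quantile-mapping bias correction of model-derived fire metrics.

Downscaled climate-model weather reproduces marginal distributions of the
raw variables but not their covariance and serial correlation, so fuel
moistures and ignition components *derived* from model weather inherit
distributional biases.  This module fits, per grid cell (optionally pooled
by calendar month), paired empirical quantile tables of a model-derived
metric against pseudo-observations over a common training period, and
corrects arbitrary series by monotone interpolation between the nodes, with
constant-offset extrapolation beyond the training range so modeled change
signals outside the training support are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = ["QuantileMap", "fit_quantile_map", "apply_quantile_map"]

_POOLINGS = ("all", "month")


@dataclass
class QuantileMap:
    """Paired model/observation quantile tables for one metric.

    ``model_q`` and ``obs_q`` are DataArrays with a leading ``quantile``
    dimension (and a ``month`` dimension when pooled by calendar month),
    plus whatever cell dimensions the training data carried.
    """

    model_q: xr.DataArray
    obs_q: xr.DataArray
    pooling: str = "all"

    def __post_init__(self) -> None:
        if self.pooling not in _POOLINGS:
            raise ValueError(f"pooling must be one of {_POOLINGS}")
        if self.model_q.sizes != self.obs_q.sizes:
            raise ValueError("model and observation quantile tables must align")

    def to_dataset(self) -> xr.Dataset:
        """Serializable sidecar representation."""
        return xr.Dataset({"model_q": self.model_q, "obs_q": self.obs_q},
                          attrs={"pooling": self.pooling})

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "QuantileMap":
        return cls(ds["model_q"], ds["obs_q"], ds.attrs.get("pooling", "all"))


def _fit_tables(model: xr.DataArray, obs: xr.DataArray,
                probs: np.ndarray) -> tuple[xr.DataArray, xr.DataArray]:
    mq = model.quantile(probs, dim="time")
    oq = obs.quantile(probs, dim="time")
    return mq, oq


def fit_quantile_map(model_train: xr.DataArray, obs_train: xr.DataArray,
                     n_quantiles: int = 100, pooling: str = "month") -> QuantileMap:
    """Fit empirical quantile tables over a common training period.

    Both series must share the training time axis length (values need not be
    paired in time — only the marginal distributions matter).  ``pooling``
    "month" fits one table per calendar month, capturing seasonal bias
    structure; "all" pools every training day.
    """
    if pooling not in _POOLINGS:
        raise ValueError(f"pooling must be one of {_POOLINGS}")
    if model_train.sizes.get("time", 0) == 0 or obs_train.sizes.get("time", 0) == 0:
        raise ValueError("training series must be nonempty")
    if n_quantiles < 2:
        raise ValueError("need at least two quantile nodes")
    probs = np.linspace(0.0, 1.0, n_quantiles)
    if pooling == "month":
        mq = model_train.groupby("time.month").map(lambda d: d.quantile(probs, dim="time"))
        oq = obs_train.groupby("time.month").map(lambda d: d.quantile(probs, dim="time"))
    else:
        mq, oq = _fit_tables(model_train, obs_train, probs)
    return QuantileMap(mq, oq, pooling)


def _correct_1d(x: np.ndarray, mq: np.ndarray, oq: np.ndarray) -> np.ndarray:
    """Monotone interpolation between nodes; constant-offset tails."""
    out = np.interp(x, mq, oq)
    lo, hi = mq[0], mq[-1]
    below = x < lo
    above = x > hi
    if below.any():
        out[below] = x[below] + (oq[0] - lo)
    if above.any():
        out[above] = x[above] + (oq[-1] - hi)
    return out


def apply_quantile_map(qmap: QuantileMap, series: xr.DataArray) -> xr.DataArray:
    """Correct a (time, ...) series through the fitted map.

    Rank order is preserved within each pooling stratum because each
    per-node transform is nondecreasing.
    """
    if qmap.pooling == "month":
        months = series["time"].dt.month

        def _one_month(sub: xr.DataArray) -> xr.DataArray:
            m = int(sub["time"].dt.month.values[0])
            mq = qmap.model_q.sel(month=m)
            oq = qmap.obs_q.sel(month=m)
            return xr.apply_ufunc(
                _correct_1d, sub, mq, oq,
                input_core_dims=[["time"], ["quantile"], ["quantile"]],
                output_core_dims=[["time"]], vectorize=True,
            ).transpose(*sub.dims)

        corrected = series.groupby(months.rename("month")).map(_one_month)
        return corrected.transpose(*series.dims)
    corrected = xr.apply_ufunc(
        _correct_1d, series, qmap.model_q, qmap.obs_q,
        input_core_dims=[["time"], ["quantile"], ["quantile"]],
        output_core_dims=[["time"]], vectorize=True,
    )
    return corrected.transpose(*series.dims)
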