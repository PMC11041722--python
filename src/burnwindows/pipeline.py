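"""End-to-end driver: weather -> fuel moisture -> RxDays -> counts & trends.

A :class:`PipelineConfig` (constructed in code or loaded from YAML/JSON)
fully determines one run: the synthetic weather spec or an input weather
file, the burn-plan source, the RxDay definition variant, the fuel-moisture
spin-up, regions and seasons to summarize, and the master seed.  The driver
writes rx.nc, lls.nc, per-region seasonal CSV series, a trend-summary JSON
and a manifest (config hash + seed + versions); two runs from the same
config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import xarray as xr
import yaml

from . import io as bwio
from . import prescriptions as rx
from . import stagnation, trends
from .fuel_moisture import compute_fuel_moisture_grid
from .synthetic import (SyntheticClimateSpec, VariableClimatology,
                        generate_burn_plans, generate_vegetation_mask,
                        generate_weather_grid)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("burnwindows")

DEFAULT_SEASONS = ("annual", "DJF", "MAM", "JJA", "SON")


@dataclass
class PipelineConfig:
    spec: SyntheticClimateSpec = field(default_factory=SyntheticClimateSpec)
    weather_path: str | None = None          # overrides spec when given
    plans_path: str | None = None            # JSON; else synthetic plans
    n_forest_plans: int = 14
    n_nonforest_plans: int = 8
    forest_fraction: float = 0.5
    variant: str = "veg_aware"
    spinup: int = 90
    seasons: tuple[str, ...] = DEFAULT_SEASONS
    regions: tuple[trends.RegionBox, ...] = (trends.WUS_DOMAIN,) + trends.SUBREGIONS
    seed: int = 0
    outdir: str = "burnwindows_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.variant not in rx.RX_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for s in self.seasons:
            if s not in trends.SEASON_MONTHS:
                raise ValueError(f"unknown season {s!r}")
        if self.weather_path and not Path(self.weather_path).exists():
            raise FileNotFoundError(self.weather_path)
        if self.plans_path and not Path(self.plans_path).exists():
            raise FileNotFoundError(self.plans_path)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = [dataclasses.asdict(r) for r in self.regions]
        d["seasons"] = list(self.seasons)
        return d


def load_config(path) -> PipelineConfig:
    """Config from YAML or JSON; nested spec/region blocks become dataclasses."""
    raw = yaml.safe_load(Path(path).read_text())
    spec_raw = raw.pop("spec", {})
    for name in ("tmax", "rhmin", "wind"):
        if name in spec_raw and isinstance(spec_raw[name], dict):
            spec_raw[name] = VariableClimatology(**spec_raw[name])
    if "lat_bounds" in spec_raw:
        spec_raw["lat_bounds"] = tuple(spec_raw["lat_bounds"])
    if "lon_bounds" in spec_raw:
        spec_raw["lon_bounds"] = tuple(spec_raw["lon_bounds"])
    regions = raw.pop("regions", None)
    cfg = PipelineConfig(spec=SyntheticClimateSpec(**spec_raw), **raw)
    if regions is not None:
        cfg.regions = tuple(trends.RegionBox(**r) for r in regions)
    if "seasons" in raw:
        cfg.seasons = tuple(raw["seasons"])
    return cfg


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle; returns it in memory too."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage 1/6: weather")
    if config.weather_path:
        weather = bwio.read_weather_netcdf(config.weather_path)
    else:
        weather = generate_weather_grid(config.spec)

    log.info("stage 2/6: fuel moisture (spinup=%d)", config.spinup)
    fm = compute_fuel_moisture_grid(weather, spinup=config.spinup)

    log.info("stage 3/6: burn plans and envelopes")
    if config.plans_path:
        plans = bwio.plans_from_json(config.plans_path)
    else:
        plans = generate_burn_plans(config.n_forest_plans, config.n_nonforest_plans,
                                    seed=config.seed)
    env_forest = rx.median_envelope(plans, rx.VEG_FOREST)
    env_nonforest = rx.median_envelope(plans, rx.VEG_NONFOREST)
    env_all = rx.median_envelope(plans, None)
    mask = generate_vegetation_mask(weather["lat"].values, weather["lon"].values,
                                    config.forest_fraction, seed=config.seed)

    log.info("stage 4/6: RxDay classification (variant=%s)", config.variant)
    rxdays = rx.rxday_grid(weather, fm, mask, env_forest, env_nonforest,
                           variant=config.variant, env_all=env_all)

    log.info("stage 5/6: stagnation")
    lls = stagnation.classify_lls(weather["wind10"], weather["precip"]).rename("lls")

    log.info("stage 6/6: counts, regional means, trends")
    rows = []
    trend_summary = {}
    for season in config.seasons:
        counts = trends.seasonal_counts(rxdays, season)
        for region in config.regions:
            series = trends.regional_mean(counts, region)
            for year, value in zip(series["year"].values, series.values):
                rows.append({"year": int(year), "season": season,
                             "region": region.name, "value": float(value)})
            tr = trends.linear_trend(series)
            trend_summary[f"{region.name}|{season}"] = dataclasses.asdict(tr)
    regional = pd.DataFrame(rows)

    bwio.write_bool_netcdf(rxdays, outdir / "rx.nc")
    bwio.write_bool_netcdf(lls, outdir / "lls.nc")
    bwio.write_regional_csv(regional, outdir / "regional_rxdays.csv")
    (outdir / "trends.json").write_text(
        json.dumps(trend_summary, indent=2, sort_keys=True) + "\n")
    bwio.plans_to_json(plans, outdir / "plans.json")
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "artifacts": ["rx.nc", "lls.nc", "regional_rxdays.csv", "trends.json",
                      "plans.json"],
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return {"weather": weather, "fm": fm, "rxdays": rxdays, "lls": lls,
            "regional": regional, "trends": trend_summary, "manifest": manifest,
            "envelopes": {"forest": env_forest, "non-forest": env_nonforest,
                          "all": env_all}}
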