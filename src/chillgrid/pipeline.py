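"""End-to-end orchestration: weather → correction → totals → indices → report.

The pipeline mirrors the study design it emulates: an observational
baseline (1989–2005) is regridded to the scenario grid; each mock GCM-RCM
member is bias-corrected against it with EQM; chill portions and GDH are
accumulated per cell and season; Safe Winter Chill / Safe Heat Forcing
are computed per subperiod, member and scenario; and regional statistics,
change maps and linear trends are written as tidy CSVs alongside NetCDF
fields and a JSON run manifest. Everything is a deterministic function of
(config, seed).

Northern-hemisphere accumulation windows are hardcoded; grids with
negative latitudes are rejected outright.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .bias import apply_eqm, fit_eqm, regrid_bilinear
from .grid import GridSpec
from .indices import (EnsembleSummary, change_map, ensemble_stats,
                      linear_trend, safe_index, subperiods)
from .regions import (RegionMask, extract_region, load_regions_geojson,
                      regional_boxstats)
from .synthetic import WeatherGenConfig, generate_baseline, generate_scenario_set
from .thermal import GDHParams, SeasonalTotals, seasonal_totals
from .weather import DailyWeatherSeries

logger = logging.getLogger(__name__)

GDH_REPORT_SCALE = 1e-3  # GDH/SHF are reported in units of 10^3 degree-hours


def _box_region(spec: Mapping) -> RegionMask:
    from shapely.geometry import box
    return RegionMask(region_id=spec["region_id"],
                      fruit=spec.get("fruit", ""),
                      polygon=box(spec["lon_min"], spec["lat_min"],
                                  spec["lon_max"], spec["lat_max"]))


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    seed: int = 0
    outdir: str = "chillgrid_out"
    # grids: observational (finer) and scenario (coarser) over the same span
    obs_grid_shape: tuple[int, int] = (9, 9)
    scen_grid_shape: tuple[int, int] = (8, 8)
    lat_span: tuple[float, float] = (36.5, 42.5)
    lon_span: tuple[float, float] = (-9.5, -6.0)
    # periods
    year_start: int = 1989
    hist_end: int = 2005
    future_start: int = 2021
    future_end: int = 2080
    # generator knobs (see WeatherGenConfig for meanings/units)
    generator: dict = field(default_factory=dict)
    n_models: int = 2
    scenarios: dict = field(default_factory=lambda: {"rcp45-like": 0.02,
                                                     "rcp85-like": 0.05})
    # method parameters
    n_quantiles: int = 99
    percentile_level: float = 0.1
    gdh: dict = field(default_factory=dict)
    # regions: GeoJSON path, or inline list of lat/lon boxes
    regions_geojson: str | None = None
    regions: list = field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("obs_grid_shape", "scen_grid_shape", "lat_span", "lon_span"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    # -- derived objects ----------------------------------------------------
    def obs_grid(self) -> GridSpec:
        return GridSpec(np.linspace(*self.lat_span, self.obs_grid_shape[0]),
                        np.linspace(*self.lon_span, self.obs_grid_shape[1]))

    def scen_grid(self) -> GridSpec:
        return GridSpec(np.linspace(*self.lat_span, self.scen_grid_shape[0]),
                        np.linspace(*self.lon_span, self.scen_grid_shape[1]))

    def gdh_params(self) -> GDHParams:
        return GDHParams(**self.gdh) if self.gdh else GDHParams()

    def gen_config(self, grid: GridSpec, seed_offset: int = 0,
                   year_end: int | None = None) -> WeatherGenConfig:
        return WeatherGenConfig(
            grid=grid, year_start=self.year_start,
            year_end=self.hist_end if year_end is None else year_end,
            seed=self.seed + seed_offset, **self.generator)

    def region_masks(self) -> list[RegionMask]:
        if self.regions_geojson:
            return load_regions_geojson(self.regions_geojson)
        if self.regions:
            return [_box_region(r) for r in self.regions]
        return default_demo_regions()

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_demo_regions() -> list[RegionMask]:
    """Eight synthetic box regions over the demo domain (two per fruit)."""
    fruits = ["apple", "apple", "apple", "apple", "pear", "pear", "plum",
              "orange"]
    lats = np.linspace(36.8, 42.0, 8)
    out = []
    for k, (fruit, la) in enumerate(zip(fruits, lats), start=1):
        out.append(_box_region({
            "region_id": f"region{k:02d}-{fruit}", "fruit": fruit,
            "lat_min": la - 0.5, "lat_max": la + 0.5,
            "lon_min": -9.5 + 0.4 * k, "lon_max": -9.5 + 0.4 * k + 1.2}))
    return out


def demo_config(outdir: str = "chillgrid_out", seed: int = 0) -> RunConfig:
    """The packaged demo: 8×8 scenario grid, 2 mock model pairs, 2 scenarios,
    1989–2080, with a known warm bias for the correction stage to remove."""
    return RunConfig(seed=seed, outdir=outdir,
                     generator={"noise_sd": 2.0, "ar1_coef": 0.7,
                                "bias_offset": 1.5, "bias_scale": 1.02})


# --- pipeline ----------------------------------------------------------------

class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(ctx, *a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(ctx, *a, **kw)
            except Exception as e:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {e}") from e
            ctx["manifest"]["timings_s"][name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s done in %.1fs", name,
                        ctx["manifest"]["timings_s"][name])
            return out
        return wrapper
    return deco


def _check_hemisphere(grid: GridSpec) -> None:
    if np.any(grid.lat < 0):
        raise ValueError("southern-hemisphere grids are not supported: "
                         "accumulation windows are northern-hemisphere only")


@_stage("generate")
def stage_generate(ctx: dict) -> None:
    cfg: RunConfig = ctx["config"]
    _check_hemisphere(cfg.obs_grid())
    _check_hemisphere(cfg.scen_grid())
    obs = generate_baseline(cfg.gen_config(cfg.obs_grid()))
    # scenario weather: its own realization of the same climate (seed offset),
    # with per-model biases and per-scenario post-historical warming
    members = generate_scenario_set(
        cfg.gen_config(cfg.scen_grid(), seed_offset=1), cfg.n_models,
        cfg.scenarios, hist_end_year=cfg.hist_end,
        future_end_year=cfg.future_end)
    wdir = ctx["outdir"] / "weather"
    wdir.mkdir(parents=True, exist_ok=True)
    obs.to_netcdf(wdir / "baseline_obs.nc")
    for s in members:
        s.to_netcdf(wdir / f"sim_{s.provenance.replace(':', '_')}.nc")
    ctx["obs"], ctx["members"] = obs, members


@_stage("correct")
def stage_correct(ctx: dict) -> None:
    cfg: RunConfig = ctx["config"]
    obs_rg = regrid_bilinear(ctx["obs"], cfg.scen_grid())
    cdir = ctx["outdir"] / "corrected"
    cdir.mkdir(parents=True, exist_ok=True)
    obs_rg.to_netcdf(cdir / "obs_on_scenario_grid.nc")
    corrected = []
    for s in ctx["members"]:
        hist = s.sel_years(cfg.year_start, cfg.hist_end)
        qmap = fit_eqm(obs_rg, hist, n_quantiles=cfg.n_quantiles)
        corr = apply_eqm(qmap, s)
        corr.to_netcdf(cdir / f"corr_{s.provenance.replace(':', '_')}.nc")
        corrected.append(corr)
    ctx["obs_rg"], ctx["corrected"] = obs_rg, corrected


@_stage("accumulate")
def stage_accumulate(ctx: dict) -> None:
    cfg: RunConfig = ctx["config"]
    tdir = ctx["outdir"] / "totals"
    tdir.mkdir(parents=True, exist_ok=True)
    gdh_p = cfg.gdh_params()

    def both(series: DailyWeatherSeries, tag: str):
        res = {}
        for kind in ("chill", "forcing"):
            tot = seasonal_totals(series, kind, gdh_params=gdh_p)
            tot.to_csv(tdir / f"{tag}_{tot.variable}.csv")
            res[tot.variable] = tot
        return res

    ctx["totals_obs"] = both(ctx["obs_rg"], "obs")
    ctx["totals_members"] = {}
    for s in ctx["corrected"]:
        # season for year Y needs October Y-1: keep one spin-up year
        fut = s.sel_years(cfg.future_start - 1, cfg.future_end)
        tag = s.provenance.replace(":", "_")
        ctx["totals_members"][s.provenance] = both(fut, tag)


@_stage("indices")
def stage_indices(ctx: dict) -> None:
    cfg: RunConfig = ctx["config"]
    level = cfg.percentile_level
    idir = ctx["outdir"] / "indices"
    idir.mkdir(parents=True, exist_ok=True)
    periods = subperiods(cfg.future_start, cfg.future_end)

    baseline = {
        var: safe_index(ctx["totals_obs"][var],
                        (cfg.year_start, cfg.hist_end), level=level)
        for var in ("CP", "GDH")}
    xr.Dataset({v.name: v for v in baseline.values()}).to_netcdf(
        idir / "baseline.nc", engine="scipy")

    member_idx: dict = {}   # (scenario, period_label, var) -> [per-member fields]
    for prov, totals in ctx["totals_members"].items():
        _, scen = prov.split(":")
        for var in ("CP", "GDH"):
            for label, a, b in periods:
                member_idx.setdefault((scen, label, var), []).append(
                    safe_index(totals[var], (a, b), level=level))
    ens: dict = {}
    for key, fields in member_idx.items():
        ens[key] = ensemble_stats(fields) if len(fields) > 1 else \
            EnsembleSummary(fields[0], fields[0] * 0.0, 1)
    future_vars = {}
    for (scen, label, var), summ in ens.items():
        stem = f"{'SWC' if var == 'CP' else 'SHF'}_{scen}_{label}"
        future_vars[f"{stem}_mean"] = summ.mean
        future_vars[f"{stem}_std"] = summ.std
    xr.Dataset(future_vars).to_netcdf(idir / "future.nc", engine="scipy")
    ctx["baseline_idx"], ctx["ensemble_idx"] = baseline, ens
    ctx["periods"] = periods


@_stage("report")
def stage_report(ctx: dict) -> None:
    cfg: RunConfig = ctx["config"]
    rdir = ctx["outdir"] / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    masks = cfg.region_masks()
    scen_grid = cfg.scen_grid()
    for m in masks:
        m.member_mask(scen_grid)  # fail fast on empty regions

    # -- change maps (ensemble SWC/SHF minus baseline) ------------------------
    rows = []
    for (scen, label, var), summ in ctx["ensemble_idx"].items():
        delta = change_map(summ.mean, ctx["baseline_idx"][var])
        scale = 1.0 if var == "CP" else GDH_REPORT_SCALE
        for mask in masks:
            vals = extract_region(delta, mask) * scale
            rows.append({"scenario": scen, "period": label,
                         "index": "SWC" if var == "CP" else "SHF",
                         "region": mask.region_id, "fruit": mask.fruit,
                         "mean_change": vals.mean()})
    pd.DataFrame(rows).to_csv(rdir / "changes.csv", index=False,
                              float_format="%.4f")

    # -- regional boxplot stats (pooled cell-season totals) -------------------
    rows = []
    pools = [("baseline", "baseline", ctx["totals_obs"])]
    for prov, totals in ctx["totals_members"].items():
        model, scen = prov.split(":")
        pools.append((scen, f"member:{model}", totals))
    for scen, who, totals in pools:
        for var in ("CP", "GDH"):
            scale = 1.0 if var == "CP" else GDH_REPORT_SCALE
            for mask in masks:
                vals = extract_region(totals[var].data, mask) * scale
                bs = regional_boxstats(vals, region=mask.region_id,
                                       variable=var, period=scen, scenario=scen)
                rows.append({"region": mask.region_id, "fruit": mask.fruit,
                             "variable": var, "scenario": scen, "source": who,
                             "min": bs.minimum, "q25": bs.q25, "mean": bs.mean,
                             "median": bs.median, "q75": bs.q75,
                             "max": bs.maximum})
    pd.DataFrame(rows).to_csv(rdir / "boxstats.csv", index=False,
                              float_format="%.4f")

    # -- regional trends of the annual ensemble-mean series -------------------
    rows = []
    years = np.arange(cfg.future_start, cfg.future_end + 1)
    for var in ("CP", "GDH"):
        scale = 1.0 if var == "CP" else GDH_REPORT_SCALE
        for scen in cfg.scenarios:
            per_member = [t[var].data.sel(season_year=slice(cfg.future_start,
                                                            cfg.future_end))
                          for prov, t in ctx["totals_members"].items()
                          if prov.endswith(f":{scen}")]
            ens_mean = sum(per_member) / len(per_member)
            for mask in masks:
                mm = mask.member_mask(scen_grid)
                series = np.array([
                    np.nanmean(ens_mean.sel(season_year=y).values[mm])
                    for y in years]) * scale
                tr = linear_trend(years, series, region=mask.region_id,
                                  scenario=scen)
                member_slopes = []
                for memb in per_member:
                    ms = np.array([np.nanmean(memb.sel(season_year=y).values[mm])
                                   for y in years]) * scale
                    member_slopes.append(linear_trend(years, ms).slope)
                rows.append({"region": mask.region_id, "fruit": mask.fruit,
                             "variable": var, "scenario": scen,
                             "slope_per_year": tr.slope,
                             "intercept": tr.intercept, "n_years": tr.n,
                             "resid_sd": tr.resid_sd,
                             "member_slope_min": min(member_slopes),
                             "member_slope_max": max(member_slopes)})
    pd.DataFrame(rows).to_csv(rdir / "trends.csv", index=False,
                              float_format="%.6f")
    ctx["report_dir"] = rdir


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run context with a manifest.

    Stages run in order: generate, correct (regrid + EQM), accumulate
    (CP/GDH), indices (SWC/SHF, ensemble), report (regional stats, changes,
    trends). Any failure aborts with a stage-named :class:`PipelineError`
    and the partial output directory is renamed ``<outdir>.failed``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx: dict = {"config": config, "outdir": outdir,
                 "manifest": {"config_hash": config.content_hash(),
                              "seed": config.seed, "timings_s": {},
                              "versions": _versions()}}
    try:
        stage_generate(ctx)
        stage_correct(ctx)
        stage_accumulate(ctx)
        stage_indices(ctx)
        stage_report(ctx)
    except PipelineError:
        quarantine = outdir.with_name(outdir.name + ".failed")
        if quarantine.exists():
            import shutil
            shutil.rmtree(quarantine)
        outdir.rename(quarantine)
        raise
    ctx["manifest"]["outputs"] = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file())
    (outdir / "manifest.json").write_text(
        json.dumps(ctx["manifest"], indent=2, sort_keys=True))
    return ctx


def _versions() -> dict:
    import pandas
    import xarray
    return {"chillgrid": __version__, "numpy": np.__version__,
            "pandas": pandas.__version__, "xarray": xarray.__version__}
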