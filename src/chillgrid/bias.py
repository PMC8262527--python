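"""Bilinear regridding and Empirical Quantile Mapping (EQM) bias correction.

EQM matches the empirical distribution of simulated daily temperatures to
observations quantile-by-quantile: for each grid cell, calendar month and
variable (tasmin/tasmax) the map stores paired simulated-historical and
observed quantiles at fixed probability levels (percentiles 1–99 by
default). Applying the map transforms each simulated value by
piecewise-linear interpolation between matched quantile pairs; values
outside the fitted range are shifted by the offset at the outermost
quantile (constant-shift tails), never clamped, so the transform stays
monotone on all of R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

from .grid import GridSpec
from .weather import TASMAX, TASMIN, DailyWeatherSeries

logger = logging.getLogger(__name__)

VARIABLES = (TASMIN, TASMAX)


def regrid_bilinear(series: DailyWeatherSeries,
                    target: GridSpec) -> DailyWeatherSeries:
    """Bilinear interpolation of each variable onto a target grid.

    Exact for fields linear in lat and lon. Target centers outside the
    source extent are evaluated at the nearest source edge (nearest-edge
    extrapolation); the number of clamped centers is logged.
    """
    src = series.grid
    lo_lat, hi_lat = src.lat[0], src.lat[-1]
    lo_lon, hi_lon = src.lon[0], src.lon[-1]
    if target.lat[-1] < lo_lat or target.lat[0] > hi_lat \
            or target.lon[-1] < lo_lon or target.lon[0] > hi_lon:
        raise ValueError("target grid is disjoint from the source grid")
    clip_lat = np.clip(target.lat, lo_lat, hi_lat)
    clip_lon = np.clip(target.lon, lo_lon, hi_lon)
    n_clamped = int((clip_lat != target.lat).sum() + (clip_lon != target.lon).sum())
    if n_clamped:
        logger.info("regrid: %d target coordinates clamped to source edge",
                    n_clamped)
    # evaluate at clipped positions along fresh dims (tolerates duplicates),
    # then relabel with the true target centers
    interp = series.data.interp(
        lat=xr.DataArray(clip_lat, dims="lat_t"),
        lon=xr.DataArray(clip_lon, dims="lon_t"),
        method="linear",
    ).transpose("time", "lat_t", "lon_t")
    from .weather import from_arrays
    return from_arrays(target, series.dates, interp[TASMIN].values,
                       interp[TASMAX].values, series.provenance,
                       attrs=dict(series.data.attrs))


@dataclass
class QuantileMap:
    """Fitted observed/simulated quantile pairs per cell, month and variable.

    ``sim_q`` and ``obs_q`` are Datasets with variables tasmin/tasmax of
    dims (month, level, lat, lon); ``levels`` are the probability levels
    in (0, 1).
    """

    levels: np.ndarray
    sim_q: xr.Dataset
    obs_q: xr.Dataset
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if lv.size < 2 or np.any(lv <= 0) or np.any(lv >= 1) \
                or not np.all(np.diff(lv) > 0):
            raise ValueError("levels must be >=2 increasing values in (0,1)")
        self.levels = lv
        for ds in (self.sim_q, self.obs_q):
            for v in VARIABLES:
                q = ds[v].transpose("month", "level", "lat", "lon").values
                if np.any(np.diff(q, axis=1) < -1e-9):
                    raise ValueError(f"{v} quantile vectors must be non-decreasing")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.sim_q["lat"].values, self.sim_q["lon"].values)

    def to_netcdf(self, path: str | Path) -> None:
        ds = xr.merge([self.sim_q.rename({v: f"sim_{v}" for v in VARIABLES}),
                       self.obs_q.rename({v: f"obs_{v}" for v in VARIABLES})])
        ds = ds.assign_coords(level=self.levels)
        ds.attrs.update({k: str(v) for k, v in self.meta.items()})
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "QuantileMap":
        ds = xr.open_dataset(path, engine="scipy").load()
        ds.close()
        sim = ds[[f"sim_{v}" for v in VARIABLES]].rename(
            {f"sim_{v}": v for v in VARIABLES})
        obs = ds[[f"obs_{v}" for v in VARIABLES]].rename(
            {f"obs_{v}": v for v in VARIABLES})
        return cls(ds["level"].values, sim, obs, meta=dict(ds.attrs))


def fit_eqm(obs: DailyWeatherSeries, sim_hist: DailyWeatherSeries,
            n_quantiles: int = 99) -> QuantileMap:
    """Fit an EQM map from overlapping observed and simulated-historical data.

    Pools days by calendar month across all years of the overlap; tasmin
    and tasmax are treated independently. Quantiles use the linear
    interpolation convention h = (n−1)p + 1. Any cell-month pool smaller
    than 30 days is an error naming the pool.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    if obs.grid != sim_hist.grid:
        raise ValueError("obs and sim_hist must share a grid")
    t0 = max(obs.dates[0], sim_hist.dates[0])
    t1 = min(obs.dates[-1], sim_hist.dates[-1])
    if t0 > t1:
        raise ValueError("obs and sim_hist periods do not overlap")
    obs_d = obs.sel_window(t0, t1)
    sim_d = sim_hist.sel_window(t0, t1)

    levels = np.arange(1, n_quantiles + 1) / (n_quantiles + 1.0)
    months = np.arange(1, 13)

    def month_quantiles(ds: xr.Dataset, label: str) -> xr.Dataset:
        per_var = {}
        for v in VARIABLES:
            arr = ds[v]
            stacks = []
            for m in months:
                pool = arr.sel(time=arr["time.month"] == m)
                if pool.sizes.get("time", 0) < 30:
                    raise ValueError(
                        f"{label}: cell-month pool {v}/month={m} has "
                        f"{pool.sizes.get('time', 0)} days (< 30)")
                q = np.quantile(pool.values, levels, axis=0)  # (nq, nlat, nlon)
                stacks.append(q)
            per_var[v] = (("month", "level", "lat", "lon"), np.stack(stacks))
        return xr.Dataset(per_var, coords={"month": months, "level": levels,
                                           "lat": ds["lat"].values,
                                           "lon": ds["lon"].values})

    qm = QuantileMap(
        levels,
        month_quantiles(sim_d, "sim_hist"),
        month_quantiles(obs_d, "obs"),
        meta={"fit_start": str(t0.date()), "fit_end": str(t1.date()),
              "n_quantiles": n_quantiles, "n_days": int(obs_d.sizes["time"])},
    )
    return qm


def _map_values(x: np.ndarray, sim_q: np.ndarray, obs_q: np.ndarray) -> np.ndarray:
    """Piecewise-linear quantile transform with constant-shift tails."""
    y = np.interp(x, sim_q, obs_q)
    lo, hi = sim_q[0], sim_q[-1]
    below = x < lo
    above = x > hi
    if below.any():
        y[below] = x[below] + (obs_q[0] - lo)
    if above.any():
        y[above] = x[above] + (obs_q[-1] - hi)
    return y


def apply_eqm(qmap: QuantileMap, sim: DailyWeatherSeries) -> DailyWeatherSeries:
    """Bias-correct a simulated series with a fitted quantile map.

    Each value is transformed by its cell/month/variable map. If the
    independent correction of tasmin and tasmax inverts a pair, the pair is
    swap-repaired and the count logged.
    """
    if qmap.grid != sim.grid:
        raise ValueError("quantile map grid does not match the series grid")
    months = sim.dates.month.values
    out = sim.data.copy(deep=True)
    nlat, nlon = sim.grid.shape
    for v in VARIABLES:
        vals = out[v].values
        sim_q = qmap.sim_q[v].transpose("month", "level", "lat", "lon").values
        obs_q = qmap.obs_q[v].transpose("month", "level", "lat", "lon").values
        for m in range(1, 13):
            sel = months == m
            if not sel.any():
                continue
            for i in range(nlat):
                for j in range(nlon):
                    vals[sel, i, j] = _map_values(
                        vals[sel, i, j], sim_q[m - 1, :, i, j],
                        obs_q[m - 1, :, i, j])
        out[v].values[:] = vals
    tmin, tmax = out[TASMIN].values, out[TASMAX].values
    inverted = tmin > tmax
    if inverted.any():
        logger.info("apply_eqm: swap-repaired %d inverted tmin/tmax pairs",
                    int(inverted.sum()))
        lo = np.minimum(tmin, tmax)
        hi = np.maximum(tmin, tmax)
        out[TASMIN].values[:] = lo
        out[TASMAX].values[:] = hi
    out.attrs = dict(sim.data.attrs)
    out.attrs["bias_corrected"] = "eqm"
    return DailyWeatherSeries(out, provenance=sim.provenance)
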