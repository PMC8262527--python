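"""Daily Tmin/Tmax series on a grid — the universal pipeline input.

The container wraps an :class:`xarray.Dataset` with CF-style layout
(dimensions ``time, lat, lon``; variables ``tasmin``/``tasmax`` in °C) so
that NetCDF round-trips are trivial, and adds the invariants downstream
stages rely on: a gap-free daily calendar and ``tasmin <= tasmax``
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec

TASMIN = "tasmin"
TASMAX = "tasmax"


@dataclass
class DailyWeatherSeries:
    """Per-cell daily minimum/maximum 2-m air temperature (°C).

    ``provenance`` labels the series origin: ``"observed"`` for the
    baseline, or ``"<model>:<scenario>"`` for a simulated member.
    """

    data: xr.Dataset
    provenance: str = "observed"

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ----------------------------------------------------------
    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.data["lat"].values, self.data["lon"].values)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["time"].values)

    @property
    def tmin(self) -> xr.DataArray:
        return self.data[TASMIN]

    @property
    def tmax(self) -> xr.DataArray:
        return self.data[TASMAX]

    def validate(self) -> None:
        for v in (TASMIN, TASMAX):
            if v not in self.data:
                raise ValueError(f"missing variable {v!r}")
        dates = self.dates
        if len(dates) == 0:
            raise ValueError("empty time axis")
        expected = pd.date_range(dates[0], dates[-1], freq="D")
        if len(dates) != len(expected) or not (dates == expected).all():
            raise ValueError("date axis has gaps or is unsorted")
        tmin = self.data[TASMIN].values
        tmax = self.data[TASMAX].values
        bad = np.isfinite(tmin) & np.isfinite(tmax) & (tmin > tmax)
        if bad.any():
            raise ValueError(f"tasmin > tasmax on {int(bad.sum())} cell-days")
        self.data.attrs.setdefault("provenance", self.provenance)
        self.provenance = self.data.attrs["provenance"]

    # -- selection ----------------------------------------------------------
    def sel_years(self, year_start: int, year_end: int) -> "DailyWeatherSeries":
        """Sub-series covering calendar years [year_start, year_end]."""
        sub = self.data.sel(time=slice(f"{year_start}-01-01", f"{year_end}-12-31"))
        return DailyWeatherSeries(sub, provenance=self.provenance)

    def sel_window(self, start: pd.Timestamp, end: pd.Timestamp) -> xr.Dataset:
        return self.data.sel(time=slice(start, end))

    # -- I/O -----------------------------------------------------------------
    def to_netcdf(self, path: str | Path) -> None:
        ds = self.data.copy()
        ds.attrs["provenance"] = self.provenance
        for v in (TASMIN, TASMAX):
            ds[v].attrs.setdefault("units", "degC")
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "DailyWeatherSeries":
        ds = xr.open_dataset(path, engine="scipy").load()
        ds.close()
        return cls(ds, provenance=str(ds.attrs.get("provenance", "observed")))

    def to_site_csv(self, path: str | Path, lat: float, lon: float) -> None:
        """Write a single-site CSV (date,tmin,tmax) for the nearest cell."""
        cell = self.data.sel(lat=lat, lon=lon, method="nearest")
        pd.DataFrame({
            "date": self.dates.strftime("%Y-%m-%d"),
            "tmin": cell[TASMIN].values,
            "tmax": cell[TASMAX].values,
        }).to_csv(path, index=False)

    @classmethod
    def from_site_csv(cls, path: str | Path, lat: float, lon: float,
                      provenance: str = "observed") -> "DailyWeatherSeries":
        """Read a per-site CSV into a 1×1-cell series at (lat, lon)."""
        df = pd.read_csv(path, parse_dates=["date"])
        ds = xr.Dataset(
            {TASMIN: (("time", "lat", "lon"), df["tmin"].values[:, None, None]),
             TASMAX: (("time", "lat", "lon"), df["tmax"].values[:, None, None])},
            coords={"time": df["date"].values,
                    "lat": [float(lat)], "lon": [float(lon)]},
        )
        return cls(ds, provenance=provenance)


def from_arrays(grid: GridSpec, dates: pd.DatetimeIndex, tmin: np.ndarray,
                tmax: np.ndarray, provenance: str,
                attrs: dict | None = None) -> DailyWeatherSeries:
    """Assemble a series from raw (time, lat, lon) arrays."""
    ds = xr.Dataset(
        {TASMIN: (("time", "lat", "lon"), tmin),
         TASMAX: (("time", "lat", "lon"), tmax)},
        coords={"time": dates, "lat": grid.lat, "lon": grid.lon},
        attrs={"provenance": provenance, **(attrs or {})},
    )
    return DailyWeatherSeries(ds, provenance=provenance)
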