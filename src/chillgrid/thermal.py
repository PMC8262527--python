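"""Chilling (Dynamic model, Chill Portions) and forcing (Growing Degree Hours).

The Dynamic model is a two-step kinetic model of dormancy chilling: each
hour an intermediate product relaxes first-order toward a
temperature-dependent equilibrium ``xs`` with temperature-dependent rate
``k1``; whenever the intermediate reaches 1, a sigmoid-in-temperature
fraction ``xi`` converts irreversibly into fixed "chill portions" (CP) and
the remainder carries over. Warm hours can destroy not-yet-fixed
intermediate — the model's hallmark chill-negation effect. Temperatures
enter the rate laws in kelvin; the canonical published constants are the
defaults. Effective chilling spans roughly −16…24 °C with an optimum near
4–6 °C; one portion accumulates per ~25–30 h near the optimum.

Growing Degree Hours (GDH) accumulate forcing heat with a cosine response
between a base temperature Tb (no growth), an optimum Tu, and a critical
temperature Tc above which accumulation stops: 0 outside [Tb, Tc], a
half-cosine ramp on [Tb, Tu] peaking at F*(Tu − Tb), and a quarter-cosine
decline on (Tu, Tc].

Accumulation windows follow orchard practice for the study system: chill
from 1 October (year−1) through end of February (year); forcing from
1 February through 31 October. Northern-hemisphere windows only.
"""

from __future__ import annotations

import calendar
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import xarray as xr

from .hourly import HourlyTemperatureSeries, hourly_grid
from .weather import DailyWeatherSeries

logger = logging.getLogger(__name__)

Kind = Literal["chill", "forcing"]


@dataclass(frozen=True)
class DynamicModelParams:
    """Canonical Dynamic-model constants (kelvin-based rate laws)."""

    slp: float = 1.6          # sigmoid slope of the conversion fraction
    tetmlt: float = 277.0     # K, transition temperature of the sigmoid
    a0: float = 1.395e5       # rate prefactor, formation
    a1: float = 2.567e18      # rate prefactor, destruction
    e0: float = 4153.5        # K, activation energy, formation
    e1: float = 12888.8       # K, activation energy, destruction

    def __post_init__(self) -> None:
        if min(self.slp, self.tetmlt, self.a0, self.a1, self.e0, self.e1) <= 0:
            raise ValueError("all Dynamic-model constants must be positive")
        if not self.a1 > self.a0:
            raise ValueError("a1 must exceed a0")


@dataclass(frozen=True)
class GDHParams:
    """GDH cosine-response parameters (°C) and stress factor F."""

    tb: float = 4.0
    tu: float = 25.0
    tc: float = 36.0
    f: float = 1.0

    def __post_init__(self) -> None:
        if not self.tb < self.tu < self.tc:
            raise ValueError("need Tb < Tu < Tc")
        if not 0 < self.f <= 1:
            raise ValueError("stress factor F must be in (0, 1]")


@dataclass(frozen=True)
class SeasonWindow:
    """One accumulation window, labelled by its season year."""

    kind: Kind
    season_year: int
    start_date: pd.Timestamp
    end_date: pd.Timestamp


# --- chill portions ---------------------------------------------------------

def chill_portions(
    hourly: HourlyTemperatureSeries | np.ndarray,
    params: DynamicModelParams = DynamicModelParams(),
) -> tuple[np.ndarray, np.ndarray | float]:
    """Cumulative chill portions over an hourly temperature record.

    Accepts a single-site :class:`HourlyTemperatureSeries` or a raw array
    with hours on axis 0 (trailing axes are independent cells). Returns
    ``(cumulative, total)`` where ``cumulative`` has the input's shape and
    is non-decreasing along the hour axis; NaN input hours poison the
    affected cell's totals (seasons with gaps are reported missing, never
    silently bridged).
    """
    if isinstance(hourly, HourlyTemperatureSeries):
        temps = hourly.temperature
    else:
        temps = np.asarray(hourly, dtype=float)
    if temps.shape[0] == 0:
        raise ValueError("empty hourly window")

    tk = temps + 273.0
    with np.errstate(over="ignore", invalid="ignore"):
        sr = np.exp(params.slp * params.tetmlt * (tk - params.tetmlt) / tk)
        xi = sr / (1.0 + sr)
        xs = (params.a0 / params.a1) * np.exp((params.e1 - params.e0) / tk)
        decay = np.exp(-params.a1 * np.exp(-params.e1 / tk))

    inter_s = np.zeros(temps.shape[1:])
    portions = np.zeros(temps.shape[1:])
    cum = np.empty_like(temps)
    for h in range(temps.shape[0]):
        inter_e = xs[h] - (xs[h] - inter_s) * decay[h]
        converting = inter_e >= 1.0
        delt = np.where(converting, inter_e * xi[h], 0.0)
        inter_s = inter_e - delt
        portions = portions + delt
        cum[h] = portions
    gap = np.isnan(temps).any(axis=0)
    if np.any(gap):
        cum[..., gap] = np.nan
    total = cum[-1]
    return cum, (float(total) if total.ndim == 0 else total)


# --- growing degree hours ---------------------------------------------------

def gdh_hour(temp_c: np.ndarray | float,
             params: GDHParams = GDHParams()) -> np.ndarray | float:
    """Degree-hours contributed by one hour at ``temp_c`` (vectorized)."""
    t = np.asarray(temp_c, dtype=float)
    span = params.tu - params.tb
    ramp = params.f * span / 2.0 * (
        1.0 + np.cos(np.pi + np.pi * (t - params.tb) / span))
    decline = params.f * span * (
        1.0 + np.cos(np.pi / 2.0 + np.pi / 2.0 * (t - params.tu)
                     / (params.tc - params.tu)))
    out = np.where(t <= params.tu, ramp, decline)
    out = np.where((t <= params.tb) | (t >= params.tc), 0.0, out)
    out = np.where(np.isnan(t), np.nan, out)
    return float(out) if out.ndim == 0 else out


def gdh_accumulate(hourly: HourlyTemperatureSeries, window: SeasonWindow,
                   params: GDHParams = GDHParams()) -> float:
    """Sum of hourly GDH over a forcing window (raw degree-hours)."""
    if window.kind != "forcing":
        raise ValueError("gdh_accumulate needs a forcing window")
    ts = hourly.timestamps
    mask = (ts >= window.start_date) & (ts < window.end_date + pd.Timedelta(days=1))
    if ts[mask].normalize().nunique() != (window.end_date - window.start_date).days + 1:
        raise ValueError("hourly series does not cover the window")
    return float(np.sum(gdh_hour(hourly.temperature[mask], params)))


# --- season windows ----------------------------------------------------------

def _february_end(year: int) -> pd.Timestamp:
    return pd.Timestamp(year, 2, 29 if calendar.isleap(year) else 28)


def season_window(kind: Kind, season_year: int) -> SeasonWindow:
    """The chill or forcing window labelled ``season_year``."""
    if kind == "chill":
        return SeasonWindow("chill", season_year,
                            pd.Timestamp(season_year - 1, 10, 1),
                            _february_end(season_year))
    if kind == "forcing":
        return SeasonWindow("forcing", season_year,
                            pd.Timestamp(season_year, 2, 1),
                            pd.Timestamp(season_year, 10, 31))
    raise ValueError(f"unknown window kind {kind!r}")


def season_windows(years: Iterable[int], kind: Kind,
                   coverage: tuple[pd.Timestamp, pd.Timestamp] | None = None,
                   ) -> list[SeasonWindow]:
    """Windows for the requested season years, dropping uncovered ones.

    With ``coverage`` given (first/last available dates), seasons whose
    window is not fully inside the data are omitted with a warning — e.g.
    the first chill season of a series starting 1 January lacks the
    preceding autumn.
    """
    out = []
    for y in years:
        w = season_window(kind, int(y))
        if coverage is not None and (w.start_date < coverage[0]
                                     or w.end_date > coverage[1]):
            warnings.warn(f"{kind} season {y} not fully covered by data; "
                          "omitted", stacklevel=2)
            continue
        out.append(w)
    return out


# --- gridded seasonal totals --------------------------------------------------

@dataclass
class SeasonalTotals:
    """Per-cell, per-season-year totals of CP or GDH.

    ``data`` has dims (season_year, lat, lon); GDH is stored in raw
    degree-hours — any ×10³ scaling happens only at reporting time.
    """

    data: xr.DataArray
    variable: Literal["CP", "GDH"]

    def __post_init__(self) -> None:
        finite = self.data.values[np.isfinite(self.data.values)]
        if (finite < -1e-9).any():
            raise ValueError("seasonal totals must be >= 0")

    def to_csv(self, path: str | Path) -> None:
        df = self.data.to_dataframe(name="value").reset_index()
        df["variable"] = self.variable
        df.to_csv(path, index=False, float_format="%.6f")

    def to_netcdf(self, path: str | Path) -> None:
        ds = self.data.to_dataset(name=self.variable)
        ds.attrs["variable"] = self.variable
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "SeasonalTotals":
        ds = xr.open_dataset(path, engine="scipy").load()
        ds.close()
        var = str(ds.attrs.get("variable", list(ds.data_vars)[0]))
        return cls(ds[var], var)  # type: ignore[arg-type]


def seasonal_totals(daily: DailyWeatherSeries, kind: Kind,
                    chill_params: DynamicModelParams = DynamicModelParams(),
                    gdh_params: GDHParams = GDHParams()) -> SeasonalTotals:
    """CP or GDH totals for every complete season in a gridded daily series.

    Each window is reconstructed to hourly resolution (with one padding day
    on either side so the diurnal curve has true neighbours) and fed to the
    corresponding thermal model. A cell-season containing any missing day
    yields NaN.
    """
    dates = daily.dates
    first_label = dates[0].year
    last_label = dates[-1].year + 1
    windows = season_windows(range(first_label, last_label + 1), kind,
                             coverage=(dates[0], dates[-1]))
    if not windows:
        raise ValueError("no complete seasons in series")

    nlat, nlon = daily.grid.shape
    totals = np.full((len(windows), nlat, nlon), np.nan)
    for i, w in enumerate(windows):
        pad_start = max(w.start_date - pd.Timedelta(days=1), dates[0])
        pad_end = min(w.end_date + pd.Timedelta(days=1), dates[-1])
        block = daily.sel_window(pad_start, pad_end)
        sub = DailyWeatherSeries(block, provenance=daily.provenance)
        cube, ts = hourly_grid(sub)
        in_win = np.asarray((ts >= w.start_date)
                            & (ts < w.end_date + pd.Timedelta(days=1)))
        temps = cube[in_win]
        if kind == "chill":
            _, tot = chill_portions(temps, chill_params)
        else:
            tot = np.nansum(gdh_hour(temps, gdh_params), axis=0)
            tot = np.where(np.isnan(temps).any(axis=0), np.nan, tot)
        totals[i] = tot
    n_missing = int(np.isnan(totals).sum())
    if n_missing:
        logger.info("%d cell-seasons missing in %s totals", n_missing, kind)
    da = xr.DataArray(
        totals,
        coords={"season_year": [w.season_year for w in windows],
                "lat": daily.grid.lat, "lon": daily.grid.lon},
        dims=("season_year", "lat", "lon"),
        name="CP" if kind == "chill" else "GDH",
    )
    da.attrs["provenance"] = daily.provenance
    return SeasonalTotals(da, "CP" if kind == "chill" else "GDH")
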