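"""Daily-to-hourly temperature reconstruction.

Implements the widely used idealized diurnal curve: between sunrise and
sunset the temperature follows a sine from Tmin (at sunrise) up to Tmax,

    T(h) = Tmin + (Tmax - Tmin) * sin(pi * (h - sunrise) / (daylength + 4)),

whose peak falls at 14:00 solar time; after sunset it decays
logarithmically from the sunset-hour temperature toward the next day's
Tmin at the next sunrise,

    T(h) = T_sunset - (T_sunset - Tmin_next) * ln(max(h - sunset, 1)) / ln(nightlength).

Pre-dawn hours continue the previous night's curve, so the series is
continuous across day boundaries. The first/last days of a series are
self-padded (used as their own neighbours) and this is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solar import daylength_hours
from .weather import DailyWeatherSeries

logger = logging.getLogger(__name__)


@dataclass
class HourlyTemperatureSeries:
    """Hourly temperatures (°C) for one site; 24 values per calendar day."""

    timestamps: pd.DatetimeIndex
    temperature: np.ndarray
    site_id: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        if len(self.timestamps) != self.temperature.size:
            raise ValueError("timestamps/temperature length mismatch")
        if self.temperature.size % 24 != 0:
            raise ValueError("series must hold 24 values per day")
        if not np.all(np.isfinite(self.temperature)):
            raise ValueError("non-finite hourly temperatures")

    def to_csv(self, path) -> None:
        pd.DataFrame({"timestamp": self.timestamps,
                      "temp_C": self.temperature}).to_csv(path, index=False)


def hourly_curve(tmin: np.ndarray, tmax: np.ndarray, doys: np.ndarray,
                 latitude: np.ndarray | float) -> np.ndarray:
    """Vectorized diurnal curve on integer hours 0..23.

    Parameters
    ----------
    tmin, tmax : ndarray, shape (ndays, *cells)
    doys : ndarray, shape (ndays,), day-of-year per day
    latitude : scalar or array broadcastable to the cell dims

    Returns
    -------
    ndarray, shape (ndays, 24, *cells)
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    ndays = tmin.shape[0]
    if ndays < 3:
        raise ValueError("need at least 3 consecutive days")
    cell_nd = tmin.ndim - 1
    doy_r = np.asarray(doys).reshape((ndays,) + (1,) * cell_nd)

    dl = np.clip(daylength_hours(latitude, doy_r), 0.1, 23.9)
    sunrise = 12.0 - dl / 2.0
    sunset = 12.0 + dl / 2.0
    t_sunset = tmin + (tmax - tmin) * np.sin(np.pi * dl / (dl + 4.0))

    prev = np.r_[0, np.arange(ndays - 1)]   # self-padded neighbours
    nxt = np.r_[np.arange(1, ndays), ndays - 1]

    def ex(a):  # (ndays, *cells) -> (ndays, 1, *cells)
        return a[:, None, ...]

    hours = np.arange(24.0).reshape((1, 24) + (1,) * cell_nd)

    # daytime sine
    day_val = ex(tmin) + (ex(tmax) - ex(tmin)) * np.sin(
        np.pi * (hours - ex(sunrise)) / (ex(dl) + 4.0))

    # pre-dawn: previous day's decay toward today's Tmin at today's sunrise
    t_pre = hours + 24.0 - ex(sunset[prev])
    nl_pre = ex(sunrise) + 24.0 - ex(sunset[prev])
    pre_val = ex(t_sunset[prev]) - (ex(t_sunset[prev]) - ex(tmin)) * (
        np.log(np.maximum(t_pre, 1.0)) / np.log(np.maximum(nl_pre, 1.0 + 1e-9)))

    # post-sunset: decay toward tomorrow's Tmin at tomorrow's sunrise
    t_post = hours - ex(sunset)
    nl_post = ex(sunrise[nxt]) + 24.0 - ex(sunset)
    post_val = ex(t_sunset) - (ex(t_sunset) - ex(tmin[nxt])) * (
        np.log(np.maximum(t_post, 1.0)) / np.log(np.maximum(nl_post, 1.0 + 1e-9)))

    out = np.where(hours < ex(sunrise), pre_val,
                   np.where(hours <= ex(sunset), day_val, post_val))
    return out


def hourly_grid(daily: DailyWeatherSeries) -> tuple[np.ndarray, pd.DatetimeIndex]:
    """Hourly temperatures for every cell of a gridded daily series.

    Returns an array of shape (ndays*24, nlat, nlon) plus hourly timestamps.
    """
    dates = daily.dates
    tmin = daily.tmin.values
    tmax = daily.tmax.values
    lat = daily.grid.lat[:, None]  # broadcast over lon
    cube = hourly_curve(tmin, tmax, dates.dayofyear.values, lat)
    ndays, _, nlat, nlon = cube.shape
    ts = pd.date_range(dates[0], periods=ndays * 24, freq="h")
    return cube.reshape(ndays * 24, nlat, nlon), ts


def interpolate_hourly(daily: DailyWeatherSeries,
                       latitude: float | None = None,
                       site_id: str = "") -> HourlyTemperatureSeries:
    """Hourly series for a single-cell daily series.

    ``latitude`` defaults to the cell's grid latitude. Needs >= 3 days; the
    series edges are self-padded (first/last day stand in for the missing
    neighbour), which is logged.
    """
    if daily.grid.ncells != 1:
        raise ValueError("interpolate_hourly expects a single-cell series; "
                         "use hourly_grid for gridded input")
    if latitude is None:
        latitude = float(daily.grid.lat[0])
    dates = daily.dates
    if len(dates) >= 3:
        logger.debug("edge days self-padded for %s", site_id or daily.provenance)
    tmin = daily.tmin.values[:, 0, 0]
    tmax = daily.tmax.values[:, 0, 0]
    vals = hourly_curve(tmin, tmax, dates.dayofyear.values, latitude)
    ts = pd.date_range(dates[0], periods=len(dates) * 24, freq="h")
    return HourlyTemperatureSeries(ts, vals.reshape(-1), site_id=site_id)
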