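"""Photoperiod geometry: sunrise, sunset and daylength from latitude and day.

Uses the Cooper (1969) solar declination,

    delta = 23.45 sin(2*pi*(284 + doy)/365),

and the standard sunset-hour-angle relation cos(H) = -tan(lat) tan(delta),
with daylength 2H/15 hours. Solar noon is fixed at 12:00 local solar time
(no longitude/timezone correction): thermal sums downstream are insensitive
to a constant phase shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: latitude beyond which polar day/night can occur; results are clamped there
POLAR_LAT = 66.5


@dataclass(frozen=True)
class SolarTimes:
    """Sunrise/sunset in hours of local solar time, plus daylength."""

    sunrise: float
    sunset: float
    daylength: float


def declination(day_of_year: np.ndarray | float) -> np.ndarray | float:
    """Solar declination in degrees for a day of year (1–366)."""
    return 23.45 * np.sin(2.0 * np.pi * (284.0 + np.asarray(day_of_year)) / 365.0)


def daylength_hours(latitude: np.ndarray | float,
                    day_of_year: np.ndarray | float) -> np.ndarray:
    """Daylength in hours; clamped into [0, 24] at polar latitudes."""
    decl = np.radians(declination(day_of_year))
    lat = np.radians(np.asarray(latitude, dtype=float))
    cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 2.0 * np.degrees(np.arccos(cos_h)) / 15.0


def solar_times(latitude: float, day_of_year: int) -> SolarTimes:
    """Sunrise/sunset/daylength for one latitude and day of year.

    Latitudes poleward of 66.5° are accepted but the daylength is clamped
    into [0, 24] (polar day/night) and a warning is emitted.
    """
    if not 1 <= int(day_of_year) <= 366:
        raise ValueError("day_of_year must be in 1..366")
    if abs(latitude) > POLAR_LAT:
        warnings.warn(
            f"latitude {latitude} is poleward of {POLAR_LAT}; daylength "
            "clamped to [0, 24] h (polar day/night)", stacklevel=2)
    dl = float(daylength_hours(latitude, day_of_year))
    return SolarTimes(sunrise=12.0 - dl / 2.0, sunset=12.0 + dl / 2.0,
                      daylength=dl)
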