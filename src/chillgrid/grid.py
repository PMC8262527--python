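"""Regular lat/lon grid description (cell-center registration)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """A regular latitude/longitude grid, cell-center registered.

    Parameters
    ----------
    lat : array-like
        Cell-center latitudes in degrees north, strictly ascending, |lat| < 90.
    lon : array-like
        Cell-center longitudes in degrees east, strictly ascending.
    """

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        if lat.ndim != 1 or lon.ndim != 1 or lat.size < 1 or lon.size < 1:
            raise ValueError("grid needs 1-D, non-empty lat and lon centers")
        if lat.size > 1 and not np.all(np.diff(lat) > 0):
            raise ValueError("lat centers must be strictly ascending")
        if lon.size > 1 and not np.all(np.diff(lon) > 0):
            raise ValueError("lon centers must be strictly ascending")
        if np.any(np.abs(lat) >= 90):
            raise ValueError("|lat| must be < 90")
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    @property
    def ncells(self) -> int:
        return self.lat.size * self.lon.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (self.lat.shape == other.lat.shape
                and self.lon.shape == other.lon.shape
                and np.allclose(self.lat, other.lat)
                and np.allclose(self.lon, other.lon))

    def __hash__(self) -> int:  # frozen dataclass with arrays
        return hash((self.lat.tobytes(), self.lon.tobytes()))


def portugal_like_grid(n_lat: int = 8, n_lon: int = 8) -> GridSpec:
    """Default demo grid spanning 36.5–42.5°N, 9.5–6.0°W (mainland-Portugal-like)."""
    return GridSpec(lat=np.linspace(36.5, 42.5, n_lat),
                    lon=np.linspace(-9.5, -6.0, n_lon))
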