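"""Region masks and regional summary statistics.

A region is a named set of grid cells — given either as an explicit list
of (lat_index, lon_index) pairs or as a polygon (a cell belongs to the
region if its center lies inside the polygon). Regions carry a fruit
label so per-crop summaries can be grouped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import xarray as xr
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec

logger = logging.getLogger(__name__)


@dataclass
class RegionMask:
    """One fruit region: polygon- or index-defined set of grid cells."""

    region_id: str
    fruit: str = ""
    polygon: BaseGeometry | None = None
    cells: Sequence[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.polygon is None and self.cells is None:
            raise ValueError("region needs a polygon or explicit cells")

    def member_mask(self, grid: GridSpec) -> np.ndarray:
        """Boolean (nlat, nlon) membership array; errors if empty."""
        mask = np.zeros(grid.shape, dtype=bool)
        if self.cells is not None:
            for i, j in self.cells:
                mask[i, j] = True
        else:
            for i, la in enumerate(grid.lat):
                for j, lo in enumerate(grid.lon):
                    if self.polygon.contains(Point(lo, la)):
                        mask[i, j] = True
        if not mask.any():
            raise ValueError(
                f"region {self.region_id!r} intersects no grid cells")
        return mask


def load_regions_geojson(path: str | Path) -> list[RegionMask]:
    """Read regions from a GeoJSON FeatureCollection.

    Each feature needs properties ``region_id`` (unique) and optionally
    ``fruit``; geometry is any polygon type.
    """
    gj = json.loads(Path(path).read_text())
    out, seen = [], set()
    for feat in gj["features"]:
        rid = feat["properties"]["region_id"]
        if rid in seen:
            raise ValueError(f"duplicate region id {rid!r}")
        seen.add(rid)
        out.append(RegionMask(region_id=rid,
                              fruit=feat["properties"].get("fruit", ""),
                              polygon=shape(feat["geometry"])))
    return out


def extract_region(field: xr.DataArray, mask: RegionMask) -> np.ndarray:
    """Values of the region's member cells, missing cells dropped (logged)."""
    m = mask.member_mask(GridSpec(field["lat"].values, field["lon"].values))
    vals = field.values[..., m]  # leading dims (e.g. season_year) preserved
    flat = vals.reshape(-1)
    n_missing = int(np.isnan(flat).sum())
    if n_missing:
        logger.info("region %s: dropped %d missing cell values",
                    mask.region_id, n_missing)
    return flat[np.isfinite(flat)]


@dataclass
class RegionalBoxStats:
    """Order statistics of a regional value pool (boxplot summary)."""

    region: str
    variable: str = ""
    period: str = ""
    scenario: str = ""
    minimum: float = np.nan
    q25: float = np.nan
    mean: float = np.nan
    median: float = np.nan
    q75: float = np.nan
    maximum: float = np.nan


def regional_boxstats(values: np.ndarray, region: str = "",
                      variable: str = "", period: str = "",
                      scenario: str = "") -> RegionalBoxStats:
    """Min/q25/mean/median/q75/max of a pool of regional values.

    Quantiles use the same linear-interpolation convention as the safe
    indices; the mean is arithmetic.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("regional_boxstats needs at least one value")
    return RegionalBoxStats(
        region=region, variable=variable, period=period, scenario=scenario,
        minimum=float(v.min()), q25=float(np.quantile(v, 0.25)),
        mean=float(v.mean()), median=float(np.median(v)),
        q75=float(np.quantile(v, 0.75)), maximum=float(v.max()))
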