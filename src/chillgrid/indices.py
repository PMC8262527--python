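"""Safe Winter Chill / Safe Heat Forcing, ensemble statistics and trends.

Safe Winter Chill (SWC) is the 10th percentile of annual chill-portion
totals over a period — the chill a grower can count on in 90% of years;
Safe Heat Forcing (SHF) is the same percentile of annual GDH totals.
Percentiles use linear interpolation between order statistics with
plotting position h = (n−1)p + 1 (numpy's default). Ensemble statistics
across model pairs use the arithmetic mean and the population standard
deviation (the members enumerate the ensemble, they are not a sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import xarray as xr

from .thermal import SeasonalTotals

#: the three future subperiods compared against the baseline
SUBPERIOD_LABELS = ("2021-2040", "2041-2060", "2061-2080")


def subperiods(year_start: int = 2021, year_end: int = 2080,
               n_periods: int = 3) -> list[tuple[str, int, int]]:
    """Disjoint contiguous equal-length (label, start, end) year ranges."""
    n_years = year_end - year_start + 1
    if n_years % n_periods:
        raise ValueError("period span must divide evenly")
    width = n_years // n_periods
    out = []
    for k in range(n_periods):
        a = year_start + k * width
        b = a + width - 1
        out.append((f"{a}-{b}", a, b))
    return out


def safe_index(totals: SeasonalTotals, period: tuple[int, int],
               level: float = 0.1, min_seasons: int = 5) -> xr.DataArray:
    """Per-cell 10th-percentile index (SWC for CP, SHF for GDH) over a period.

    Cells with fewer than ``min_seasons`` non-missing seasons in the period
    are reported as NaN. GDH-based values stay in raw degree-hours.
    """
    y0, y1 = period
    sel = totals.data.sel(season_year=slice(y0, y1))
    if sel.sizes["season_year"] == 0:
        raise ValueError(f"no seasons inside period {y0}-{y1}")
    vals = sel.values
    n_ok = np.isfinite(vals).sum(axis=0)
    with np.errstate(all="ignore"):
        idx = np.nanquantile(vals, level, axis=0)
    idx = np.where(n_ok >= min_seasons, idx, np.nan)
    name = "SWC" if totals.variable == "CP" else "SHF"
    out = xr.DataArray(idx, coords={"lat": sel["lat"], "lon": sel["lon"]},
                       dims=("lat", "lon"), name=name)
    out.attrs.update({"period": f"{y0}-{y1}", "level": level,
                      "variable": totals.variable,
                      "n_seasons": int(sel.sizes["season_year"])})
    return out


@dataclass
class EnsembleSummary:
    """Cellwise mean and population std across ensemble members."""

    mean: xr.DataArray
    std: xr.DataArray
    n_members: int


def ensemble_stats(members: Sequence[xr.DataArray]) -> EnsembleSummary:
    """Arithmetic mean and population (ddof=0) std across model pairs."""
    if len(members) < 2:
        raise ValueError("need at least 2 ensemble members")
    ref = members[0]
    for m in members[1:]:
        if m.shape != ref.shape or not np.allclose(m["lat"], ref["lat"]) \
                or not np.allclose(m["lon"], ref["lon"]):
            raise ValueError("ensemble members have mismatched geometry")
    stack = np.stack([m.values for m in members])
    mean = ref.copy(data=stack.mean(axis=0))
    std = ref.copy(data=stack.std(axis=0, ddof=0))
    return EnsembleSummary(mean=mean, std=std, n_members=len(members))


@dataclass
class TrendEstimate:
    """OLS trend of a regional annual index series against calendar year."""

    region: str
    scenario: str
    slope: float        # index units per year
    intercept: float
    n: int
    resid_sd: float


def linear_trend(years: np.ndarray, values: np.ndarray, region: str = "",
                 scenario: str = "") -> TrendEstimate:
    """Ordinary-least-squares slope of an annual series (units per year)."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 3:
        raise ValueError("need >= 3 non-missing years for a trend")
    x, y = years[ok], values[ok]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = max(len(y) - 2, 1)
    return TrendEstimate(region=region, scenario=scenario,
                         slope=float(slope), intercept=float(intercept),
                         n=int(len(y)),
                         resid_sd=float(np.sqrt((resid ** 2).sum() / dof)))


def change_map(future: xr.DataArray, baseline: xr.DataArray) -> xr.DataArray:
    """Cellwise future − baseline of an index field (same geometry)."""
    if future.shape != baseline.shape \
            or not np.allclose(future["lat"], baseline["lat"]) \
            or not np.allclose(future["lon"], baseline["lon"]):
        raise ValueError("change_map needs identical geometry")
    delta = future - baseline
    delta.name = f"delta_{future.name or 'index'}"
    delta.attrs["future_period"] = future.attrs.get("period", "")
    delta.attrs["baseline_period"] = baseline.attrs.get("period", "")
    return delta
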