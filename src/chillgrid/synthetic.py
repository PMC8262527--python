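"""Synthetic daily-weather generator.

Emulates (a) an observational gridded baseline with seasonal cycle,
latitudinal gradient and AR(1) interannual/day-to-day variability, and
(b) simulated historical+future series for several mock GCM-RCM "model
pairs" under named scenarios, with known additive/multiplicative biases
and known imposed warming — so every downstream stage of the pipeline can
be tested against ground truth without external data.

The daily-mean temperature model is

    T(d) = T0 + g·(lat − lat_ref) + A·cos(2π(doy − peak_doy)/365.25)
           + trend·(t − t0) + ε(d),     ε AR(1)

with tmax/tmin = T ± diurnal_range/2 plus small independent perturbations
(swap-repaired so tmin ≤ tmax always holds). Scenario series share the
baseline's stochastic draws over the historical overlap, then add a
scenario-specific warming ramp; each model pair applies its own affine
bias T ↦ scale·T + offset, recorded in the series attributes for test
assertions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, portugal_like_grid
from .weather import DailyWeatherSeries, from_arrays

#: day-of-year of the warmest day (northern-hemisphere mid-July)
PEAK_DOY = 196

#: extra warming (°C/yr, applied after the historical segment) used when a
#: scenario is given by label only; magnitudes in line with moderate vs
#: severe radiative-forcing pathways over 2021–2080.
DEFAULT_SCENARIO_TRENDS: dict[str, float] = {"rcp45-like": 0.02, "rcp85-like": 0.05}


@dataclass(frozen=True)
class WeatherGenConfig:
    """Parameters of the synthetic weather generator.

    Defaults describe a mainland-Portugal-like temperate domain: ~15 °C
    annual mean at 39.5°N, cooling ~0.8 °C per degree northward, 7 °C
    seasonal half-amplitude, 10 °C diurnal range, red day-to-day noise.
    """

    grid: GridSpec = dataclasses.field(default_factory=portugal_like_grid)
    year_start: int = 1989
    year_end: int = 2005
    mean_annual_T: float = 15.0      # °C at lat_ref
    lat_ref: float = 39.5            # degrees north
    lat_gradient: float = -0.8       # °C per degree latitude
    seasonal_amplitude: float = 7.0  # °C
    diurnal_range: float = 10.0      # °C
    ar1_coef: float = 0.7            # unitless, |.| < 1
    noise_sd: float = 2.0            # °C (stationary sd of the AR(1) term)
    warming_trend: float = 0.0       # °C per year
    bias_offset: float = 0.0         # °C, scenario series only
    bias_scale: float = 1.0          # unitless, scenario series only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        if not self.diurnal_range > 0:
            raise ValueError("diurnal_range must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not abs(self.ar1_coef) < 1:
            raise ValueError("|ar1_coef| must be < 1")
        for name in ("mean_annual_T", "lat_gradient", "seasonal_amplitude",
                     "warming_trend", "bias_offset", "bias_scale"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _daily_mean_cycle(config: WeatherGenConfig,
                      dates: pd.DatetimeIndex) -> np.ndarray:
    """Deterministic daily-mean field, shape (ndays, nlat, 1)."""
    doy = dates.dayofyear.values.astype(float)
    years_elapsed = (dates - dates[0]).days.values / 365.25
    seasonal = config.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - PEAK_DOY) / 365.25)
    base = config.mean_annual_T + seasonal + config.warming_trend * years_elapsed
    lat_term = config.lat_gradient * (config.grid.lat - config.lat_ref)
    return base[:, None, None] + lat_term[None, :, None]


def _noise_fields(config: WeatherGenConfig, ndays: int) -> tuple[np.ndarray, ...]:
    """AR(1) daily-mean anomaly plus independent tmin/tmax perturbations.

    Separate deterministic substreams per component keep the first N days
    identical whenever only the series length differs — scenario series can
    therefore share the baseline's historical draws exactly.
    """
    nlat, nlon = config.grid.shape
    shape = (ndays, nlat, nlon)
    if config.noise_sd == 0:
        z = np.zeros(shape)
        return z, z.copy(), z.copy()
    innov = np.random.default_rng([config.seed, 1]).standard_normal(shape)
    innov *= config.noise_sd * np.sqrt(1.0 - config.ar1_coef ** 2)
    eps = np.empty(shape)
    eps[0] = innov[0] / np.sqrt(1.0 - config.ar1_coef ** 2)
    for d in range(1, ndays):
        eps[d] = config.ar1_coef * eps[d - 1] + innov[d]
    eta_min = np.random.default_rng([config.seed, 2]).standard_normal(shape)
    eta_max = np.random.default_rng([config.seed, 3]).standard_normal(shape)
    half = 0.5 * config.noise_sd
    return eps, half * eta_min, half * eta_max


def _assemble(config: WeatherGenConfig, dates: pd.DatetimeIndex,
              extra: np.ndarray | float, provenance: str,
              attrs: dict | None = None) -> DailyWeatherSeries:
    mean = _daily_mean_cycle(config, dates) + np.asarray(extra)
    eps, eta_min, eta_max = _noise_fields(config, len(dates))
    tmin = mean + eps - config.diurnal_range / 2.0 + eta_min
    tmax = mean + eps + config.diurnal_range / 2.0 + eta_max
    lo = np.minimum(tmin, tmax)  # swap-repair: tmin <= tmax always
    hi = np.maximum(tmin, tmax)
    return from_arrays(config.grid, dates, lo, hi, provenance, attrs)


def generate_baseline(config: WeatherGenConfig) -> DailyWeatherSeries:
    """Generate an observational-baseline-like daily Tmin/Tmax grid.

    Deterministic under a fixed ``config.seed``; with ``noise_sd=0`` the
    output is the closed-form sinusoid plus trend exactly.
    """
    dates = pd.date_range(f"{config.year_start}-01-01",
                          f"{config.year_end}-12-31", freq="D")
    return _assemble(config, dates, 0.0, "observed")


def generate_scenario_set(
    config: WeatherGenConfig,
    n_models: int,
    scenarios: Sequence[str] | Mapping[str, float],
    *,
    hist_end_year: int | None = None,
    future_end_year: int = 2080,
) -> list[DailyWeatherSeries]:
    """Generate biased historical+future series for mock GCM-RCM pairs.

    Each scenario shares one synthetic truth with the baseline over the
    historical segment (ending at ``hist_end_year``, default the config's
    ``year_end``) and adds ``trend_extra`` °C/yr of warming after it. Model
    pair 0 carries exactly the config's ``bias_offset``/``bias_scale``;
    further pairs get distinct affine biases drawn deterministically from
    the seed. True biases and trends are recorded in each series' attrs.

    ``scenarios`` maps scenario label -> extra trend (°C/yr); a plain list
    of labels is resolved against :data:`DEFAULT_SCENARIO_TRENDS`.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if isinstance(scenarios, Mapping):
        scen_map = dict(scenarios)
    else:
        try:
            scen_map = {s: DEFAULT_SCENARIO_TRENDS[s] for s in scenarios}
        except KeyError as e:
            raise ValueError(
                f"unknown scenario label {e.args[0]!r}: pass a mapping "
                "label -> extra trend (degC/yr) instead") from None
    if not scen_map:
        raise ValueError("scenario list is empty")

    hist_end = config.year_end if hist_end_year is None else hist_end_year
    dates = pd.date_range(f"{config.year_start}-01-01",
                          f"{future_end_year}-12-31", freq="D")
    years_past_hist = np.maximum(
        0.0, (dates - pd.Timestamp(f"{hist_end}-12-31")).days.values / 365.25)

    # distinct per-model biases, deterministic in the seed; model 0 uses the
    # config values verbatim so tests can impose an exact known bias
    rng = np.random.default_rng([config.seed, 999])
    offsets = [config.bias_offset]
    scales = [config.bias_scale]
    for _ in range(1, n_models):
        offsets.append(config.bias_offset + float(rng.normal(0.0, 1.5)))
        scales.append(config.bias_scale * float(np.exp(rng.normal(0.0, 0.03))))

    out: list[DailyWeatherSeries] = []
    for label, trend_extra in scen_map.items():
        ramp = (trend_extra * years_past_hist)[:, None, None]
        truth = _assemble(config, dates, ramp, "truth")
        for m in range(n_models):
            model = f"model{m + 1:02d}"
            ds = truth.data.copy(deep=True)
            for v in ("tasmin", "tasmax"):
                ds[v] = scales[m] * ds[v] + offsets[m]
            prov = f"{model}:{label}"
            ds.attrs.update({
                "provenance": prov,
                "true_bias_offset": offsets[m],
                "true_bias_scale": scales[m],
                "scenario_trend_extra": trend_extra,
                "hist_end_year": hist_end,
            })
            out.append(DailyWeatherSeries(ds, provenance=prov))
    return out
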