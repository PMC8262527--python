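# Methods

This note documents the models implemented in `chillgrid`, the
conventions chosen where the underlying literature leaves freedom, what
the synthetic weather generator does and does not emulate, and the
numerical choices that affect results.

## Thermal models

### Dynamic model (Chill Portions)

Chilling is accumulated hourly by a two-step kinetic scheme. With
temperature `T_K` in kelvin, each hour the labile intermediate `x`
relaxes first-order toward a temperature-dependent equilibrium:

    xs  = (a0/a1) · exp((e1 − e0)/T_K)          equilibrium level
    k1  = a1 · exp(−e1/T_K)                     relaxation rate
    x ← xs − (xs − x) · exp(−k1)

Whenever `x` reaches 1, a sigmoidal fraction converts irreversibly to
chill portions and the remainder carries over:

    xi = sr/(1+sr),  sr = exp(slp · tetmlt · (T_K − tetmlt)/T_K)
    ΔCP = x · xi,    x ← x − ΔCP

Constants are the canonical published set: `slp = 1.6`,
`tetmlt = 277 K`, `a0 = 1.395×10⁵`, `a1 = 2.567×10¹⁸`, `e0 = 4153.5 K`,
`e1 = 12888.8 K`. The intermediate is reset to 0 at each season start.
Consequences worth knowing:

- effective chilling spans roughly −16…24 °C; under constant
  temperatures the 720-h total peaks at 6 °C (24.43 CP, one portion per
  ~29.5 h) with 4 °C close behind (21.25 CP) — the "optimum near 4 °C"
  is a plateau, not a point;
- below the effective range the conversion sigmoid is ~10⁻¹⁹, so totals
  are zero at any reported precision but not a literal float zero
  (720 h at −20 °C gives ~1.4×10⁻¹⁵ CP);
- CP is path-dependent: permuting the hours of a season changes the
  total (warm hours destroy unconverted intermediate).

### Growing Degree Hours

Forcing heat per hour at temperature `T` (°C), with base `Tb = 4`,
optimum `Tu = 25`, critical `Tc = 36`, stress factor `F = 1`:

    0                                                    T ≤ Tb or T ≥ Tc
    F·(Tu−Tb)/2 · (1 + cos(π + π(T−Tb)/(Tu−Tb)))         Tb < T ≤ Tu
    F·(Tu−Tb)   · (1 + cos(π/2 + (π/2)(T−Tu)/(Tc−Tu)))   Tu < T < Tc

Both branches equal `F·(Tu−Tb)` = 21 degree-hours at the optimum; the
response is continuous on all of ℝ and memoryless (totals are invariant
to hour order). GDH is stored in raw degree-hours; the conventional ×10³
scaling is applied only in reports.

### Accumulation windows

Chill: 1 October (year−1) through the end of February (29 February in
leap years), labelled by the year containing January–February. Forcing:
1 February – 31 October. Seasons whose window is not fully covered by
the data are omitted with a warning (a series starting 1 January 1989
yields chill seasons 1990–2005). Windows are northern-hemisphere only;
southern-hemisphere grids are rejected explicitly. A missing day inside
a window marks that cell-season missing; gaps are never interpolated.

## Daily→hourly reconstruction

Both thermal models need hourly input, so daily extremes are expanded
with the standard idealized diurnal curve: between sunrise and sunset

    T(h) = Tmin + (Tmax − Tmin) · sin(π (h − sunrise)/(DL + 4)),

which places the daily maximum at 14:00 solar time (so the sampled
hourly maximum equals Tmax exactly), and after sunset a logarithmic
decay from the sunset-hour temperature toward the next day's Tmin at
the next sunrise. Sunrise/sunset come from the Cooper declination
`δ = 23.45° sin(2π(284+doy)/365)` with `cos H = −tan φ tan δ`; solar
noon is fixed at 12:00 local solar time (no longitude correction — a
constant phase shift does not change thermal sums). Latitudes poleward
of 66.5° are clamped with a warning. Series edges are self-padded (the
first/last day stands in for its missing neighbour). Hourly values are
always bounded by the three-day neighbourhood's extremes.

## Bias correction

Observations are first regridded to the scenario grid by per-day
bilinear interpolation (exact for fields linear in lat/lon); target
centers outside the source extent are evaluated at the nearest edge and
counted.

EQM is fitted per cell, calendar month and variable (tasmin and tasmax
independently) over the baseline/simulated-historical overlap, storing
empirical quantiles at percentiles 1–99 (the `h = (n−1)p + 1` linear
interpolation convention, numpy's default). Any cell-month pool below
30 days is an error. Application is piecewise-linear between matched
quantile pairs; outside the fitted range values are shifted by the
offset at the outermost quantile (constant-shift tails), keeping the
transform monotone and unclamped. If independent correction inverts a
tmin/tmax pair it is swap-repaired and counted. Trend-preserving
variants (quantile delta mapping) are out of scope.

## Indices, ensembles, trends

SWC/SHF are the 10th empirical percentile (same convention as above) of
annual totals within a period; cells with fewer than 5 seasons are
missing. Future subperiods are 2021–2040, 2041–2060, 2061–2080.
Ensemble statistics across model pairs are the arithmetic mean and the
*population* standard deviation (ddof = 0): the members enumerate the
ensemble rather than sample a larger population. Regional trends are
OLS slopes of the annual ensemble-mean regional series against calendar
year (per-member slopes are emitted alongside for spread); no
significance testing is attached, slopes only. Region membership is by
cell center inside the polygon, or by explicit index list; both
representations extract identically.

## Synthetic weather generator

Daily mean temperature is

    T(d) = T₀ + g·(lat − lat_ref) + A·cos(2π(doy − 196)/365.25)
           + trend·years + ε(d),

with `tmax/tmin = T ± diurnal_range/2` plus smaller independent
perturbations (sd `noise_sd/2`), swap-repaired so `tmin ≤ tmax` always.
`ε` is a stationary AR(1) with coefficient `ar1_coef` and standard
deviation `noise_sd`. Defaults describe a mainland-Portugal-like
domain: 15 °C at 39.5 °N, −0.8 °C per degree latitude northward, 7 °C
seasonal half-amplitude peaking on day 196, 10 °C diurnal range,
`ar1 = 0.7`, `noise_sd = 2 °C`. The calendar is proleptic Gregorian
with real leap days.

Scenario series share the baseline's stochastic draws over the
historical segment (per-component substreams make the overlap exactly
reproducible), then add a scenario-specific warming ramp after the
historical end — 0.02 °C/yr for the moderate and 0.05 °C/yr for the
severe default scenario, in line with mid-range vs high-end forcing
pathways over 2021–2080. Each mock model pair applies a known affine
bias `T ↦ scale·T + offset` (pair 1 uses the configured values
verbatim, e.g. the demo's +1.5 °C / ×1.02; further pairs draw distinct
biases deterministically from the seed); true biases and trends are
recorded in the series attributes so tests can assert recovery.

What the generator does *not* emulate: spatially correlated weather
(cells share the regional anomaly but have independent cell noise),
precipitation/humidity, weather extremes beyond Gaussian AR(1) tails,
realistic GCM internal variability (model pairs differ only by affine
bias, so ensemble spread is much smaller than in real archives), or the
statistics of any real dataset. Passing tests therefore demonstrate the
*machinery* — correct thermal accounting, bias-correction recovery of
known distortions, index and trend arithmetic — not skill on real data.

## Problem sizes and determinism

The packaged demo uses a 9×9 observational grid regridded to an 8×8
scenario grid, 2 model pairs × 2 scenarios over 1989–2080 — small
enough to iterate on while exercising every stage; the same pipeline
runs unchanged on larger grids. All randomness flows from a single
integer seed through named substreams; reruns are byte-identical,
and the manifest records the config hash, seed and library versions.

## Known limitations

- The exact hourly-curve variant, EQM discretization and chill-season
  start convention differ across published toolchains; the choices here
  (documented above) are internally consistent and oracle-tested, but
  absolute CP/GDH values can shift by a few percent under other
  conventions.
- The Dynamic-model hour loop is plain numpy over cells; very large
  grids (≫10⁴ cells × decades) would warrant a compiled kernel.
- EQM corrects marginal distributions per month; it does not correct
  the simulated day-to-day autocorrelation that chill negation is
  sensitive to.
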