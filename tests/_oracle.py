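"""Independent brute-force oracles for the thermal and hourly cores.

Everything here is deliberately scalar, loop-based Python written from the
published model definitions, sharing no code with the package. Tests compare
package output against these implementations on small fixtures.
"""

import math

# --- photoperiod ------------------------------------------------------------

def oracle_daylength(latitude, doy):
    """Daylength (h) from the Cooper (1969) declination and the standard
    sunset-hour-angle relation."""
    decl = 23.45 * math.sin(2.0 * math.pi * (284 + doy) / 365.0)
    x = -math.tan(math.radians(latitude)) * math.tan(math.radians(decl))
    x = min(1.0, max(-1.0, x))
    return 2.0 * math.degrees(math.acos(x)) / 15.0


def oracle_hourly_day(tmin_prev, tmax_prev, tmin, tmax, tmin_next,
                      latitude, doy_prev, doy, doy_next):
    """24 hourly temperatures for one day of a 3-day neighbourhood.

    Daytime: sine from Tmin at sunrise, T = Tmin + (Tmax-Tmin)*sin(pi*(h-sr)/(DL+4)).
    Night: logarithmic decay from the sunset-hour temperature toward the next
    sunrise's Tmin.
    """
    def sun(dl):
        return 12.0 - dl / 2.0, 12.0 + dl / 2.0

    dl_p = oracle_daylength(latitude, doy_prev)
    dl = oracle_daylength(latitude, doy)
    dl_n = oracle_daylength(latitude, doy_next)
    sr_p, ss_p = sun(dl_p)
    sr, ss = sun(dl)
    sr_n, _ = sun(dl_n)

    def t_sunset(lo, hi, d):
        return lo + (hi - lo) * math.sin(math.pi * d / (d + 4.0))

    out = []
    for h in range(24):
        if h < sr:
            tss = t_sunset(tmin_prev, tmax_prev, dl_p)
            t = h + 24.0 - ss_p
            nl = sr + 24.0 - ss_p
            val = tss - (tss - tmin) * math.log(max(t, 1.0)) / math.log(nl)
        elif h <= ss:
            val = tmin + (tmax - tmin) * math.sin(math.pi * (h - sr) / (dl + 4.0))
        else:
            tss = t_sunset(tmin, tmax, dl)
            t = h - ss
            nl = sr_n + 24.0 - ss
            val = tss - (tss - tmin_next) * math.log(max(t, 1.0)) / math.log(nl)
        out.append(val)
    return out


# --- Dynamic model (chill portions) ----------------------------------------

def oracle_chill_portions(temps_c, slp=1.6, tetmlt=277.0, a0=139500.0,
                          a1=2.567e18, e0=4153.5, e1=12888.8):
    """Step-by-step two-intermediate kinetic recursion; returns the list of
    cumulative chill portions after each hour."""
    inter_s = 0.0
    portions = 0.0
    out = []
    for t in temps_c:
        tk = t + 273.0
        ftmprt = slp * tetmlt * (tk - tetmlt) / tk
        sr = math.exp(ftmprt)
        xi = sr / (1.0 + sr)
        xs = (a0 / a1) * math.exp((e1 - e0) / tk)
        ak1 = a1 * math.exp(-e1 / tk)
        inter_e = xs - (xs - inter_s) * math.exp(-ak1)
        if inter_e < 1.0:
            inter_s = inter_e
        else:
            delt = inter_e * xi
            portions += delt
            inter_s = inter_e - delt
        out.append(portions)
    return out


# --- Growing degree hours ---------------------------------------------------

def oracle_gdh_hour(t, tb=4.0, tu=25.0, tc=36.0, f=1.0):
    if t <= tb or t >= tc:
        return 0.0
    if t <= tu:
        return f * (tu - tb) / 2.0 * (
            1.0 + math.cos(math.pi + math.pi * (t - tb) / (tu - tb)))
    return f * (tu - tb) * (
        1.0 + math.cos(math.pi / 2.0 + math.pi / 2.0 * (t - tu) / (tc - tu)))


def oracle_gdh_total(temps_c, **kw):
    return sum(oracle_gdh_hour(t, **kw) for t in temps_c)
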