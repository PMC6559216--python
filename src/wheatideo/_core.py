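"""Fast scalar core of the daily season loop.

This module holds one function, :func:`season_core`, written against plain
floats and arrays so that numba can compile it; without numba the identical
Python code runs, just slower.  It mirrors, day for day, the semantics of the
operation-level functions in :mod:`phenology`, :mod:`canopy`, :mod:`soil`
and :mod:`carbon` (a test replays a season through those operations and
checks agreement).  The wrapper in :mod:`season` converts between dataclasses
and the flat parameter arrays used here.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly by every season simulation
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

# Index layout of the cultivar-parameter vector (CultivarParams field order).
(I_PH, I_PP, I_TT_SOWEM, I_TT_ANBGF, I_TT_BGFEGF, I_TT_EGFMAT, I_AMAX,
 I_LMIN, I_LMAX, I_VAI, I_VBEE, I_HSGNT, I_HSGNR, I_DSGNT, I_DSGNS,
 I_DSGNRMAX, I_MAXGW, I_GNEAR, I_SG, I_RU, I_WSA, I_WSS) = range(22)

# Index layout of the config vector.
(C_LAT, C_IRRIGATED, C_CO2F, C_LUE, C_K, C_RUE, C_EARFRAC, C_ANTHLAG,
 C_DLREF, C_FLNSCALE, C_TBASE, C_DSFWIN, C_ROOT0, C_ROOTRATE, C_FAILSAFE,
 C_TOPT, C_FSURF, C_LAYERTHICK, C_PARFRAC, C_LEAF1FRAC, C_PLANTS) = range(21)

# Index layout of the output vector.
(O_YIELD, O_BIOMASS, O_HI, O_EMERGENCE, O_ANTHESIS, O_BGF, O_EGF, O_MATURITY,
 O_LAI_ANTH, O_CUM_RAD, O_DSF, O_HEAT_RED, O_DROUGHT_RED, O_FLN,
 O_ANTH_BIOMASS, O_GRAIN_NUMBER, O_FAILED, O_CUM_PAR, O_DRAINAGE,
 O_UPTAKE, O_RAIN_IN) = range(21)
N_OUT = 21

_PT_ALPHA = 1.26
_PSYCHROMETRIC = 0.066
_LATENT_HEAT = 2.45
_NET_RAD_FRACTION = 0.8


@njit(cache=True)
def _day_length(latitude: float, doy: int) -> float:
    decl = -23.44 * math.cos(2.0 * math.pi * (doy + 10) / 365.0)
    cos_h = -math.tan(math.radians(latitude)) * math.tan(math.radians(decl))
    if cos_h > 1.0:
        cos_h = 1.0
    elif cos_h < -1.0:
        cos_h = -1.0
    return 24.0 * math.acos(cos_h) / math.pi


@njit(cache=True)
def _expanded_area(haun: float, fln: float, a_max: float, leaf1_frac: float) -> float:
    n = int(math.ceil(fln))
    total = 0.0
    for r in range(1, n + 1):
        frac = haun - (r - 1)
        if frac <= 0.0:
            break
        if frac > 1.0:
            frac = 1.0
        if n == 1:
            pot = a_max
        else:
            pot = (leaf1_frac + (1.0 - leaf1_frac) * (r - 1) / (n - 1)) * a_max
        total += frac * pot
    return total


@njit(cache=True)
def season_core(tmin, tmax, rain, rad, doy0, cv, cf, soil_cap, soil_w):
    """Simulate one season from sowing; returns the flat output vector.

    ``tmin/tmax/rain/rad`` start on the sowing day; ``doy0`` is the sowing
    day of year (1-based, 365-day calendar); ``cv`` and ``cf`` are the
    cultivar and config vectors; ``soil_cap``/``soil_w`` are per-layer
    capacities and initial water (``soil_w`` is modified in place).
    """
    n_days = min(len(tmin), int(cf[C_FAILSAFE]))
    n_layers = len(soil_cap)
    layer_thick = cf[C_LAYERTHICK]
    max_depth = n_layers * layer_thick
    irrigated = cf[C_IRRIGATED] > 0.5

    out = np.zeros(N_OUT)
    out[O_EMERGENCE] = -1.0
    out[O_ANTHESIS] = -1.0
    out[O_BGF] = -1.0
    out[O_EGF] = -1.0
    out[O_MATURITY] = -1.0
    out[O_DSF] = 1.0

    # Phenology state
    cum_tt = 0.0
    haun = 0.0
    vern = 0.0
    fln = -1.0                       # unset
    emerged = False
    anthesis_tt = -1.0
    begin_gf_tt = -1.0
    end_gf_tt = -1.0

    # Canopy / carbon state
    sen_tt = 0.0
    lai = 0.0
    biomass = 0.0
    anth_biomass = 0.0
    labile = 0.0
    labile0 = 0.0
    grain_number = 0.0
    grain_mass = 0.0
    sink_cap = 0.0

    fw_prev = 1.0
    fw_hist = np.ones(n_days)
    cumtt_hist = np.zeros(n_days)

    rue_mult = cf[C_RUE] * cf[C_CO2F] * cf[C_LUE]
    window_sen = cv[I_TT_ANBGF] + cv[I_TT_BGFEGF]
    onset_sen = window_sen * cv[I_SG] / (1.0 + cv[I_SG])

    for t in range(n_days):
        t_mean = 0.5 * (tmin[t] + tmax[t])
        dtt = t_mean - cf[C_TBASE]
        if dtt < 0.0:
            dtt = 0.0
        cum_tt += dtt
        cumtt_hist[t] = cum_tt
        doy = (doy0 - 1 + t) % 365 + 1

        # --- phenology -----------------------------------------------------
        if vern < 1.0:
            rate = cv[I_VBEE] + cv[I_VAI] * t_mean
            if rate > 0.0:
                vern += rate
            if vern >= 1.0:
                vern = 1.0
                dl = _day_length(cf[C_LAT], doy)
                shortfall = cf[C_DLREF] - dl
                if shortfall < 0.0:
                    shortfall = 0.0
                fln = cv[I_LMIN] + cv[I_PP] * cf[C_FLNSCALE] * shortfall
                if fln < cv[I_LMIN]:
                    fln = cv[I_LMIN]
                if fln > cv[I_LMAX]:
                    fln = cv[I_LMAX]

        new_bgf = False
        if not emerged:
            if cum_tt >= cv[I_TT_SOWEM]:
                emerged = True
                out[O_EMERGENCE] = t
        else:
            haun += dtt / cv[I_PH]
            if out[O_ANTHESIS] < 0.0:
                fln_eff = fln if fln > 0.0 else cv[I_LMAX]
                if haun >= fln_eff + cf[C_ANTHLAG]:
                    out[O_ANTHESIS] = t
                    anthesis_tt = cum_tt
                    fln = fln_eff
                    anth_biomass = biomass
                    labile0 = 0.25 * anth_biomass
                    labile = labile0
            elif out[O_BGF] < 0.0:
                if cum_tt >= anthesis_tt + cv[I_TT_ANBGF]:
                    out[O_BGF] = t
                    begin_gf_tt = cum_tt
                    new_bgf = True
            elif out[O_EGF] < 0.0:
                if cum_tt >= begin_gf_tt + cv[I_TT_BGFEGF]:
                    out[O_EGF] = t
                    end_gf_tt = cum_tt
            elif out[O_MATURITY] < 0.0:
                if cum_tt >= end_gf_tt + cv[I_TT_EGFMAT]:
                    out[O_MATURITY] = t

        # --- canopy --------------------------------------------------------
        fln_canopy = fln if fln > 0.0 else cv[I_LMAX]
        area = _expanded_area(haun, fln_canopy, cv[I_AMAX], cf[C_LEAF1FRAC]) \
            * cf[C_PLANTS]
        green = 1.0
        if out[O_ANTHESIS] >= 0.0:
            sen_tt += dtt * (1.0 + (cv[I_WSS] - 1.0) * (1.0 - fw_prev))
            if sen_tt > onset_sen:
                if window_sen <= onset_sen:
                    green = 0.0
                else:
                    green = 1.0 - (sen_tt - onset_sen) / (window_sen - onset_sen)
                    if green < 0.0:
                        green = 0.0
        if out[O_EGF] >= 0.0:
            green = 0.0
        lai = area * green
        if out[O_ANTHESIS] == t:
            out[O_LAI_ANTH] = lai

        f_int = 1.0 - math.exp(-cf[C_K] * lai)
        par_int = cf[C_PARFRAC] * rad[t] * f_int
        out[O_CUM_RAD] += rad[t] * f_int
        out[O_CUM_PAR] += par_int

        # --- soil water ----------------------------------------------------
        if irrigated:
            fw = 1.0
        else:
            root_depth = cf[C_ROOT0] + cf[C_ROOTRATE] * cum_tt
            if root_depth > max_depth:
                root_depth = max_depth
            # infiltration (top-down cascade)
            remaining = rain[t]
            out[O_RAIN_IN] += rain[t]
            for i in range(n_layers):
                if remaining <= 0.0:
                    break
                room = soil_cap[i] - soil_w[i]
                added = room if room < remaining else remaining
                soil_w[i] += added
                remaining -= added
            out[O_DRAINAGE] += remaining
            # extractable supply
            f_surf = cf[C_FSURF]
            f_bot = cv[I_RU] / 100.0
            supply = 0.0
            for i in range(n_layers):
                top = i * layer_thick
                if top >= root_depth:
                    break
                frac = f_surf + (f_bot - f_surf) * top / root_depth
                if frac < 0.0:
                    frac = 0.0
                elif frac > 1.0:
                    frac = 1.0
                supply += soil_w[i] * frac
            demand = 0.0
            if rad[t] > 0.0 and f_int > 0.0:
                es = 0.6108 * math.exp(17.27 * t_mean / (t_mean + 237.3))
                delta = 4098.0 * es / (t_mean + 237.3) ** 2
                eq_evap = _PT_ALPHA * delta / (delta + _PSYCHROMETRIC) \
                    * _NET_RAD_FRACTION * rad[t] / _LATENT_HEAT
                if eq_evap > 0.0:
                    demand = eq_evap * f_int
            fw = 1.0 if demand <= 0.0 else min(1.0, supply / demand)
            uptake = supply if supply < demand else demand
            if uptake > 0.0:
                total_ex = 0.0
                for i in range(n_layers):
                    top = i * layer_thick
                    if top >= root_depth:
                        break
                    frac = f_surf + (f_bot - f_surf) * top / root_depth
                    if frac < 0.0:
                        frac = 0.0
                    elif frac > 1.0:
                        frac = 1.0
                    total_ex += soil_w[i] * frac
                if total_ex > 0.0:
                    for i in range(n_layers):
                        top = i * layer_thick
                        if top >= root_depth:
                            break
                        frac = f_surf + (f_bot - f_surf) * top / root_depth
                        if frac < 0.0:
                            frac = 0.0
                        elif frac > 1.0:
                            frac = 1.0
                        soil_w[i] -= uptake * (soil_w[i] * frac) / total_ex
                        if soil_w[i] < 0.0:
                            soil_w[i] = 0.0
                out[O_UPTAKE] += uptake
        fw_hist[t] = fw

        # --- grain number at the end of the heat/drought window -------------
        if new_bgf:
            heat_sum = 0.0
            fw_sum = 0.0
            fw_n = 0
            for u in range(t + 1):
                if cumtt_hist[u] >= anthesis_tt - cv[I_TT_ANBGF] \
                        and cumtt_hist[u] <= anthesis_tt + cv[I_TT_ANBGF]:
                    excess = tmax[u] - cv[I_HSGNT]
                    if excess > 0.0:
                        heat_sum += excess
                if cumtt_hist[u] >= anthesis_tt - cf[C_DSFWIN]:
                    fw_sum += fw_hist[u]
                    fw_n += 1
            heat_red = cv[I_HSGNR] * heat_sum
            if heat_red > 1.0:
                heat_red = 1.0
            dsf = fw_sum / fw_n if fw_n > 0 else 1.0
            if dsf >= cv[I_DSGNT]:
                drought_red = 0.0
            elif dsf <= cv[I_DSGNS]:
                drought_red = cv[I_DSGNRMAX]
            else:
                drought_red = cv[I_DSGNRMAX] * (cv[I_DSGNT] - dsf) \
                    / (cv[I_DSGNT] - cv[I_DSGNS])
            grain_number = cv[I_GNEAR] * cf[C_EARFRAC] * anth_biomass \
                * (1.0 - heat_red) * (1.0 - drought_red)
            sink_cap = grain_number * cv[I_MAXGW]
            out[O_HEAT_RED] = heat_red
            out[O_DROUGHT_RED] = drought_red
            out[O_DSF] = dsf
            out[O_GRAIN_NUMBER] = grain_number

        # --- biomass and grain fill -----------------------------------------
        f_temp = t_mean / cf[C_TOPT]
        if f_temp < 0.0:
            f_temp = 0.0
        elif f_temp > 1.0:
            f_temp = 1.0
        water_mult = 1.0 - cv[I_WSA] * (1.0 - fw)
        d_bio = par_int * rue_mult * f_temp * water_mult
        if d_bio < 0.0:
            d_bio = 0.0
        biomass += d_bio

        in_fill = out[O_BGF] >= 0.0 and out[O_EGF] < 0.0
        if in_fill:
            if lai > 0.0:
                release = labile0 * dtt / cv[I_TT_BGFEGF]
                if release > labile:
                    release = labile
                labile -= release
                grain_mass += d_bio + release
                if grain_mass > sink_cap:
                    grain_mass = sink_cap
                if grain_mass > biomass:
                    grain_mass = biomass
            else:
                labile = 0.0      # canopy dead: filling stops, pool forfeited

        fw_prev = fw
        if out[O_MATURITY] >= 0.0:
            break

    if out[O_ANTHESIS] < 0.0:
        out[O_FAILED] = 1.0
        grain_mass = 0.0

    out[O_YIELD] = grain_mass
    out[O_BIOMASS] = biomass
    out[O_HI] = grain_mass / biomass if biomass > 0.0 else 0.0
    out[O_FLN] = fln
    out[O_ANTH_BIOMASS] = anth_biomass
    return out
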