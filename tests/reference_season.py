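"""Independent season replay composed from the operation-level functions.

Used as an oracle for the fast core loop: it steps through the same daily
sequence (thermal time -> phenology -> canopy -> soil water -> biomass ->
grain) but exclusively via the public dataclass operations in
wheatideo.phenology / canopy / soil / carbon, with no reference to the
array core.
"""

import numpy as np

from wheatideo import canopy as cp
from wheatideo import carbon as cb
from wheatideo import phenology as ph
from wheatideo import soil as so


def reference_season(cultivar, weather, sowing_year_index, config):
    """Replay one season; returns a dict of the headline outputs."""
    start = sowing_year_index * 365 + config.sowing_doy - 1
    n = config.failsafe_days
    tmin = weather.tmin[start:start + n]
    tmax = weather.tmax[start:start + n]
    rain = weather.rain[start:start + n]
    rad = weather.rad[start:start + n]

    profile = so.soil_profile(config.soil)
    pheno = ph.PhenoState()
    can = cp.CanopyState()
    car = cb.CarbonState()
    wstate = so.WaterStressState()
    co2f = cb.co2_rue_factor(config.co2)
    max_depth = profile.max_depth_cm

    fw_prev, fw = 1.0, 1.0
    fw_hist, cumtt_hist = [], []
    lai_anthesis = 0.0
    cum_rad = 0.0
    grain_number_set = False

    for t in range(n):
        t_mean = 0.5 * (tmin[t] + tmax[t])
        dtt = ph.daily_thermal_time(tmin[t], tmax[t], config.t_base)
        doy = (config.sowing_doy - 1 + t) % 365 + 1

        pheno = ph.vernalization_step(pheno, t_mean, cultivar.vai, cultivar.vbee)
        prev_anth, prev_bgf = pheno.anthesis_das, pheno.begin_gf_das
        pheno = ph.advance_phenology(
            pheno, dtt, cultivar, t, latitude=config.latitude, doy=doy,
            anthesis_lag=config.anthesis_lag, dl_ref=config.dl_ref,
            fln_scale=config.fln_scale)
        cumtt_hist.append(pheno.cum_tt)
        if prev_anth is None and pheno.anthesis_das is not None:
            car.anthesis_biomass = car.biomass
            car.labile_initial = cb.LABILE_FRACTION * car.biomass
            car.labile = car.labile_initial
        new_bgf = prev_bgf is None and pheno.begin_gf_das is not None

        can = cp.update_canopy(can, dtt, pheno, cultivar, stress_factor=fw_prev,
                               plants_per_m2=config.plants_per_m2)
        if pheno.anthesis_das == t:
            lai_anthesis = can.lai
        f_int = 1.0 - np.exp(-config.k * can.lai)
        par_int = cp.intercepted_par(can.lai, rad[t], config.k)
        cum_rad += rad[t] * f_int

        if config.irrigated:
            fw = 1.0
        else:
            root_depth = min(max_depth,
                             config.root_depth0_cm
                             + config.root_rate_cm_per_tt * pheno.cum_tt)
            profile, _drain = so.infiltrate_and_drain(profile, rain[t])
            supply = so.extractable_supply(profile, root_depth, cultivar.r_u)
            demand = so.transpiration_demand(rad[t], t_mean, f_int)
            wstate, profile = so.water_stress_step(
                wstate, supply, demand, profile, root_depth, cultivar.r_u)
            fw = wstate.fw
        fw_hist.append(fw)

        if new_bgf:
            a_tt = pheno.anthesis_tt
            idx = [u for u in range(t + 1)
                   if a_tt - cultivar.tt_anbgf <= cumtt_hist[u]
                   <= a_tt + cultivar.tt_anbgf]
            heat = cb.heat_stress_reduction(
                [tmax[u] for u in idx], cultivar.hsgnt, cultivar.hsgnr)
            dsf_idx = [u for u in range(t + 1)
                       if cumtt_hist[u] >= a_tt - config.dsf_window_tt]
            dsf = so.drought_stress_factor([fw_hist[u] for u in dsf_idx])
            drought = cb.drought_gn_reduction(
                dsf, cultivar.dsgnt, cultivar.dsgns, cultivar.dsgnr_max)
            car.grain_number = cb.set_grain_number(
                car.anthesis_biomass, cultivar.gn_ear, config.ear_fraction,
                heat, drought)
            grain_number_set = True

        f_temp = cb.temperature_factor(t_mean, config.t_opt)
        d_bio = cb.daily_biomass_increment(
            par_int, config.rue_base, co2f, config.lue_mult, f_temp,
            fw, cultivar.w_sa)
        in_fill = grain_number_set and pheno.end_gf_das is None
        if in_fill:
            car = cb.grain_fill_step(car, d_bio, can.lai > 0.0,
                                     cultivar.max_gw, dtt, cultivar.tt_bgfegf)
        else:
            car.biomass += d_bio

        fw_prev = fw
        if pheno.maturity_das is not None:
            break

    failed = pheno.anthesis_das is None
    grain = 0.0 if failed else car.grain_mass
    return {
        "yield_t_ha": 0.01 * grain,
        "biomass_t_ha": 0.01 * car.biomass,
        "anthesis_das": -1 if pheno.anthesis_das is None else pheno.anthesis_das,
        "maturity_das": -1 if pheno.maturity_das is None else pheno.maturity_das,
        "begin_gf_das": -1 if pheno.begin_gf_das is None else pheno.begin_gf_das,
        "end_gf_das": -1 if pheno.end_gf_das is None else pheno.end_gf_das,
        "lai_anthesis": lai_anthesis,
        "cum_intercepted_rad_mj": cum_rad,
        "fln": pheno.fln,
        "failed": failed,
    }
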