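"""Biomass accumulation, grain set and grain filling.

Daily above-ground biomass is intercepted PAR times radiation use efficiency
(RUE), modified multiplicatively by CO2 (linear, +30% per doubling from
338 ppm), an optional light-use-efficiency gain, a temperature factor and
water stress (via the cultivar's photosynthetic sensitivity W_sa).

Grain number per m² is set from biomass at anthesis (a fixed ear fraction of
it) times the cultivar's grains per g of ear, reduced by heat stress around
anthesis (degree-days above the HSGNT threshold) and by drought stress (a
piecewise-linear response to the drought stress factor DSF).  During grain
fill the grain receives new assimilate plus a labile carbohydrate pool —
25% of anthesis biomass — released uniformly per unit thermal time; filling
is sink-capped at grain number × maximum grain weight and stops early if the
canopy dies, forfeiting the unreleased pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CarbonState", "co2_rue_factor", "temperature_factor",
    "daily_biomass_increment", "heat_stress_reduction", "drought_gn_reduction",
    "set_grain_number", "grain_fill_step", "harvest_index",
    "CO2_REFERENCE_PPM", "CO2_RESPONSE_PER_DOUBLING", "RUE_BASE",
    "EAR_BIOMASS_FRACTION", "LABILE_FRACTION",
]

#: Reference CO2 concentration of the RUE response (ppm).
CO2_REFERENCE_PPM = 338.0
#: Fractional RUE increase for a doubling of CO2 from the reference.
CO2_RESPONSE_PER_DOUBLING = 0.30
#: Radiation use efficiency at the reference CO2 (g DM per MJ intercepted PAR).
RUE_BASE = 2.7
#: Ear dry mass at anthesis as a fraction of above-ground biomass; calibrated
#: so the reference cultivar sets ~22-28 x 10^3 grains m-2 (10-13 t ha-1 at
#: the 0.045 g grain-weight cap) from its simulated anthesis biomass.
EAR_BIOMASS_FRACTION = 0.17
#: Labile (stem-reserve) carbohydrate pool as a fraction of anthesis biomass.
LABILE_FRACTION = 0.25


@dataclass
class CarbonState:
    """Mass pools of one crop (all g m⁻² ground)."""

    biomass: float = 0.0            # above-ground biomass
    anthesis_biomass: float = 0.0
    labile: float = 0.0             # remaining labile pool
    labile_initial: float = 0.0
    ear_mass: float = 0.0
    grain_number: float = 0.0       # grains m-2
    grain_mass: float = 0.0
    cum_par_mj: float = 0.0         # cumulative intercepted PAR (MJ m-2)
    cum_rad_mj: float = 0.0         # cumulative intercepted total solar (MJ m-2)


def co2_rue_factor(co2_ppm: float) -> float:
    """Linear RUE multiplier: 1 at 338 ppm, 1.30 at 676 ppm."""
    if co2_ppm <= 0:
        raise ValueError(f"co2 must be > 0, got {co2_ppm}")
    return 1.0 + CO2_RESPONSE_PER_DOUBLING * (co2_ppm - CO2_REFERENCE_PPM) / CO2_REFERENCE_PPM


def temperature_factor(t_mean: float, t_opt: float = 10.0) -> float:
    """Temperature limitation of daily growth: T/t_opt clamped to [0, 1]."""
    return min(1.0, max(0.0, t_mean / t_opt))


def daily_biomass_increment(par_int: float, rue_base: float, co2_factor: float,
                            lue_factor: float, f_temp: float, fw: float,
                            w_sa: float) -> float:
    """Daily above-ground biomass gain (g m⁻²).

    ``par_int × rue_base × co2_factor × lue_factor × f_temp ×
    (1 − w_sa × (1 − fw))``.  With fw = 1 the water multiplier is exactly 1;
    with full stress (fw = 0) growth is reduced by the fraction w_sa.
    """
    if not 0.0 <= f_temp <= 1.0:
        raise ValueError(f"f_temp must be in [0, 1], got {f_temp}")
    if not 0.0 <= fw <= 1.0:
        raise ValueError(f"fw must be in [0, 1], got {fw}")
    if par_int < 0:
        raise ValueError(f"par_int must be >= 0, got {par_int}")
    water_mult = 1.0 - w_sa * (1.0 - fw)
    return max(0.0, par_int * rue_base * co2_factor * lue_factor * f_temp * water_mult)


def heat_stress_reduction(tmax_window, hsgnt: float, hsgnr: float) -> float:
    """Fractional grain-number loss from heat around anthesis, in [0, 1].

    ``min(1, hsgnr × Σ max(0, tmax − hsgnt))`` over the window's days;
    zero when no day exceeds the threshold.
    """
    tmax_window = np.asarray(tmax_window, dtype=float)
    if tmax_window.size == 0:
        raise ValueError("empty tmax window")
    degree_days = np.maximum(0.0, tmax_window - hsgnt).sum()
    return float(min(1.0, hsgnr * degree_days))


def drought_gn_reduction(dsf: float, dsgnt: float, dsgns: float,
                         dsgnr_max: float) -> float:
    """Fractional grain-number loss from drought, in [0, dsgnr_max].

    Zero for DSF at or above the threshold ``dsgnt``, the maximum at or below
    the saturation ``dsgns``, linear between.
    """
    if not dsgns < dsgnt:
        raise ValueError(f"dsgns ({dsgns}) must be below dsgnt ({dsgnt})")
    if dsf >= dsgnt:
        return 0.0
    if dsf <= dsgns:
        return dsgnr_max
    return dsgnr_max * (dsgnt - dsf) / (dsgnt - dsgns)


def set_grain_number(anthesis_biomass: float, gn_ear: float, ear_fraction: float,
                     heat_red: float, drought_red: float) -> float:
    """Grains per m²: ear mass × grains/g, reduced multiplicatively by stress."""
    if not 0.0 <= ear_fraction <= 1.0:
        raise ValueError(f"ear_fraction must be in [0, 1], got {ear_fraction}")
    if not 0.0 <= heat_red <= 1.0 or not 0.0 <= drought_red <= 1.0:
        raise ValueError("stress reductions must be in [0, 1]")
    return max(0.0, gn_ear * ear_fraction * anthesis_biomass
               * (1.0 - heat_red) * (1.0 - drought_red))


def grain_fill_step(state: CarbonState, new_assim: float, canopy_alive: bool,
                    max_gw: float, dtt: float, g_f: float) -> CarbonState:
    """One day of grain filling (mutates and returns ``state``).

    The labile pool is released at ``labile_initial × dtt / g_f`` per day
    (uniform per unit thermal time over the fill window G_f).  Grain mass
    grows by new assimilate plus the release, capped at
    grain number × max grain weight.  If the canopy is dead, filling stops
    and the remaining pool is forfeited.  Total biomass still accrues the
    day's assimilate; labile release is a translocation, not new mass.
    """
    if dtt < 0 or new_assim < 0:
        raise ValueError("dtt and new_assim must be >= 0")
    state.biomass += new_assim
    if not canopy_alive:
        state.labile = 0.0
        return state
    release = min(state.labile, state.labile_initial * dtt / g_f)
    state.labile -= release
    sink_cap = state.grain_number * max_gw
    state.grain_mass = min(sink_cap, state.grain_mass + new_assim + release)
    state.grain_mass = min(state.grain_mass, state.biomass)
    return state


def harvest_index(grain_mass: float, total_biomass: float) -> float:
    """Grain mass over total above-ground biomass, in [0, 1]."""
    if total_biomass <= 0:
        raise ValueError(f"total biomass must be > 0, got {total_biomass}")
    return min(1.0, max(0.0, grain_mass / total_biomass))
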