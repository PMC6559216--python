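"""Thermal-time phenology of winter wheat.

Development is driven by accumulated thermal time above a base temperature.
Leaves appear on the mainstem at a rate of one per phyllochron (P_h); the
final leaf number (FLN) is set once the vernalization requirement saturates,
decreasing with the day length at saturation according to the day-length
response P_p.  Anthesis follows the appearance of the flag leaf by a fixed
number of phyllochrons, and the grain-fill window and maturity follow in
fixed thermal-time increments (TT_ANBGF, G_f, TT_EGFMAT).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

from .cultivar import CultivarParams

__all__ = [
    "PhenoState", "daily_thermal_time", "day_length", "vernalization_step",
    "final_leaf_number", "advance_phenology",
    "DL_REF_HOURS", "FLN_DL_SCALE", "ANTHESIS_LAG_PHYLLOCHRONS",
]

#: Day length (h) at and above which FLN stays at its minimum.
DL_REF_HOURS = 20.0
#: Leaves produced per (leaf h^-1 day length) unit of P_p per hour of
#: day-length shortfall; with 1.0 the Claire response (P_p = 0.5) spans
#: realistic FLNs of ~9-14 over winter day lengths.
FLN_DL_SCALE = 1.0
#: Phyllochrons between flag-leaf appearance (Haun stage = FLN) and anthesis.
ANTHESIS_LAG_PHYLLOCHRONS = 2.0


@dataclass(frozen=True)
class PhenoState:
    """Development state of one crop, updated daily."""

    cum_tt: float = 0.0            # thermal time since sowing (°C day)
    haun: float = 0.0              # mainstem Haun stage (leaves)
    vern_progress: float = 0.0     # vernalization progress in [0, 1]
    fln: float | None = None       # final leaf number, set at vern. saturation
    emergence_das: int | None = None
    anthesis_das: int | None = None
    begin_gf_das: int | None = None
    end_gf_das: int | None = None
    maturity_das: int | None = None
    anthesis_tt: float | None = None   # cum_tt at anthesis
    begin_gf_tt: float | None = None
    end_gf_tt: float | None = None

    @property
    def vern_saturated(self) -> bool:
        return self.vern_progress >= 1.0


def daily_thermal_time(tmin: float, tmax: float, t_base: float = 0.0) -> float:
    """Thermal time of one day: mean temperature above base, clipped at 0."""
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) below tmin ({tmin})")
    return max(0.0, 0.5 * (tmin + tmax) - t_base)


def day_length(latitude: float, doy: int) -> float:
    """Astronomical day length (hours) from the standard solar geometry.

    Solar declination follows the cosine approximation on the 365-day
    calendar.  Polar latitudes (|lat| > 66°) are rejected: no wheat site
    needs polar day/night handling.
    """
    if abs(latitude) > 66.0:
        raise ValueError(f"polar latitude {latitude} not supported (|lat| <= 66)")
    decl = -23.44 * math.cos(2.0 * math.pi * (doy + 10) / 365.0)
    cos_h = -math.tan(math.radians(latitude)) * math.tan(math.radians(decl))
    cos_h = min(1.0, max(-1.0, cos_h))
    return 24.0 * math.acos(cos_h) / math.pi


def vernalization_step(state: PhenoState, t_mean: float,
                       vai: float, vbee: float) -> PhenoState:
    """Advance vernalization by one day at mean temperature ``t_mean``.

    The daily rate is ``vbee + vai * t_mean`` (never negative); progress is
    capped at 1 (saturation).
    """
    if state.vern_saturated:
        return state
    rate = max(0.0, vbee + vai * t_mean)
    return replace(state, vern_progress=min(1.0, state.vern_progress + rate))


def final_leaf_number(cultivar: CultivarParams, dl_at_vernsat: float, *,
                      dl_ref: float = DL_REF_HOURS,
                      scale: float = FLN_DL_SCALE) -> float:
    """Final leaf number from the day length at vernalization saturation.

    FLN decreases linearly with day length at rate ``P_p * scale`` leaves per
    hour below ``dl_ref``, bounded by the cultivar's L_Min and L_Max; it is
    monotone non-increasing in day length.
    """
    fln = cultivar.l_min + cultivar.p_p * scale * max(0.0, dl_ref - dl_at_vernsat)
    return min(cultivar.l_max, max(cultivar.l_min, fln))


def advance_phenology(state: PhenoState, dtt: float, cultivar: CultivarParams,
                      das: int, *, latitude: float, doy: int,
                      anthesis_lag: float = ANTHESIS_LAG_PHYLLOCHRONS,
                      dl_ref: float = DL_REF_HOURS,
                      fln_scale: float = FLN_DL_SCALE) -> PhenoState:
    """Advance one day of development by ``dtt`` °C day.

    Order of events: thermal-time accumulation, emergence, Haun-stage
    progress (one leaf per phyllochron after emergence), anthesis at
    ``FLN + anthesis_lag`` phyllochrons, then the fixed thermal-time windows
    to begin/end of grain fill and maturity.  Vernalization is advanced
    separately (``vernalization_step``); FLN is fixed here on the day
    saturation is first seen, using that day's day length.
    """
    if dtt < 0:
        raise ValueError(f"dtt must be >= 0, got {dtt}")
    s = replace(state, cum_tt=state.cum_tt + dtt)

    if s.fln is None and s.vern_saturated:
        s = replace(s, fln=final_leaf_number(
            cultivar, day_length(latitude, doy), dl_ref=dl_ref, scale=fln_scale))

    if s.emergence_das is None:
        if s.cum_tt >= cultivar.tt_sowem:
            s = replace(s, emergence_das=das)
        return s

    s = replace(s, haun=s.haun + dtt / cultivar.p_h)

    if s.anthesis_das is None:
        # Until vernalization saturates, development proceeds toward the
        # provisional maximum leaf number (a never-vernalizing crop keeps it).
        fln_eff = s.fln if s.fln is not None else cultivar.l_max
        if s.haun >= fln_eff + anthesis_lag:
            s = replace(s, anthesis_das=das, anthesis_tt=s.cum_tt, fln=fln_eff)
        return s
    if s.begin_gf_das is None:
        if s.cum_tt >= s.anthesis_tt + cultivar.tt_anbgf:
            s = replace(s, begin_gf_das=das, begin_gf_tt=s.cum_tt)
        return s
    if s.end_gf_das is None:
        if s.cum_tt >= s.begin_gf_tt + cultivar.tt_bgfegf:
            s = replace(s, end_gf_das=das, end_gf_tt=s.cum_tt)
        return s
    if s.maturity_das is None and s.cum_tt >= s.end_gf_tt + cultivar.tt_egfmat:
        s = replace(s, maturity_das=das)
    return s
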