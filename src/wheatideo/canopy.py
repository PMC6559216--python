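"""Leaf-layer canopy, stay-green senescence and light interception.

The canopy is a stack of leaf layers, one per mainstem leaf.  Each layer's
potential area ramps linearly from 25% of the flag-leaf maximum (A_Max) for
the first leaf to A_Max for the flag leaf, and expands over one phyllochron
after the leaf appears.  After anthesis a uniform green fraction declines
linearly in *effective* senescence thermal time so that the canopy is fully
senesced exactly at the end of grain fill.  The stay-green trait S_G delays
senescence onset by the fraction S_G/(1+S_G) of the anthesis-to-end-of-fill
thermal window; water stress accelerates effective senescence time by up to
the factor W_ss.  Daily light interception follows the Beer-Lambert law with
extinction coefficient k, on PAR taken as half of global radiation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

from .cultivar import CultivarParams
from .phenology import PhenoState

__all__ = [
    "CanopyState", "potential_layer_area", "max_potential_lai",
    "expanded_area", "senescence_green_fraction", "update_canopy",
    "intercepted_par", "EXTINCTION_K", "PAR_FRACTION", "FIRST_LEAF_FRACTION",
    "PLANTS_PER_M2",
]

#: Canopy light extinction coefficient (typical for wheat).
EXTINCTION_K = 0.45
#: PAR as a fraction of global solar radiation.
PAR_FRACTION = 0.5
#: Potential area of leaf 1 as a fraction of the flag leaf's A_Max.
FIRST_LEAF_FRACTION = 0.25
#: Shoot density (mainstems per m² ground).  Layer areas are per shoot
#: (A_Max is the flag leaf's area); canopy LAI is shoot density times the
#: per-shoot green area, so cv. Claire peaks near the observed LAI ~7.7.
PLANTS_PER_M2 = 120.0


@dataclass(frozen=True)
class CanopyState:
    """Green-area state of the crop canopy."""

    lai: float = 0.0           # green leaf area index (m2 m-2)
    expanded_area: float = 0.0 # potential area expanded so far (before senescence)
    sen_tt: float = 0.0        # effective senescence thermal time since anthesis
    green_fraction: float = 1.0


def potential_layer_area(rank: int, fln: float, a_max: float) -> float:
    """Potential area of the leaf layer at ``rank`` (1 = first leaf).

    Linear ramp from ``FIRST_LEAF_FRACTION * a_max`` at rank 1 to ``a_max``
    for the flag leaf (rank = ceil(fln)); monotone non-decreasing in rank.
    """
    n = math.ceil(fln)
    if not 1 <= rank <= n:
        raise ValueError(f"rank {rank} out of range 1..{n}")
    if n == 1:
        return a_max
    frac = FIRST_LEAF_FRACTION + (1.0 - FIRST_LEAF_FRACTION) * (rank - 1) / (n - 1)
    return frac * a_max


def max_potential_lai(fln: float, a_max: float, plants_per_m2: float = 1.0) -> float:
    """Sum of all layer potential areas times shoot density.

    With the default density of 1 this is the per-shoot total area; pass
    ``PLANTS_PER_M2`` for the canopy-scale maximum achievable LAI.
    """
    per_shoot = sum(potential_layer_area(r, fln, a_max)
                    for r in range(1, math.ceil(fln) + 1))
    return per_shoot * plants_per_m2


def expanded_area(haun: float, fln: float, a_max: float) -> float:
    """Total potential area expanded by Haun stage ``haun``.

    Leaf ``r`` starts expanding when the Haun stage passes ``r - 1`` and
    expands linearly over one phyllochron.
    """
    total = 0.0
    for r in range(1, math.ceil(fln) + 1):
        frac = min(1.0, max(0.0, haun - (r - 1)))
        if frac == 0.0:
            break
        total += frac * potential_layer_area(r, fln, a_max)
    return total


def senescence_green_fraction(sen_tt: float, window_tt: float, s_g: float) -> float:
    """Uniform green fraction during post-anthesis senescence.

    ``window_tt`` is the thermal window from anthesis to the end of grain
    fill; onset is delayed by the fraction ``s_g / (1 + s_g)`` of it, after
    which the green fraction declines linearly to 0 at the window's end.
    """
    onset = window_tt * s_g / (1.0 + s_g)
    if sen_tt <= onset:
        return 1.0
    if window_tt <= onset:
        return 0.0
    return max(0.0, 1.0 - (sen_tt - onset) / (window_tt - onset))


def update_canopy(canopy: CanopyState, dtt: float, pheno: PhenoState,
                  cultivar: CultivarParams, stress_factor: float = 1.0,
                  *, fln_provisional: float | None = None,
                  plants_per_m2: float = PLANTS_PER_M2) -> CanopyState:
    """Advance the canopy by one day.

    Before anthesis leaves expand with the Haun stage.  After anthesis the
    effective senescence thermal time accumulates as
    ``dtt * (1 + (W_ss - 1) * (1 - stress_factor))`` — water stress
    (``stress_factor`` < 1) accelerates it by up to the cultivar's W_ss —
    and the green fraction declines per ``senescence_green_fraction``.  The
    canopy is forced to zero LAI once grain fill has ended.
    """
    if not 0.0 <= stress_factor <= 1.0:
        raise ValueError(f"stress_factor must be in [0, 1], got {stress_factor}")
    fln = pheno.fln if pheno.fln is not None else (
        fln_provisional if fln_provisional is not None else cultivar.l_max)
    area = expanded_area(pheno.haun, fln, cultivar.a_max) * plants_per_m2

    sen_tt = canopy.sen_tt
    green = 1.0
    if pheno.anthesis_das is not None:
        sen_tt += dtt * (1.0 + (cultivar.w_ss - 1.0) * (1.0 - stress_factor))
        window = cultivar.tt_anbgf + cultivar.tt_bgfegf
        green = senescence_green_fraction(sen_tt, window, cultivar.s_g)
    if pheno.end_gf_das is not None:
        green = 0.0
    return CanopyState(lai=area * green, expanded_area=area,
                       sen_tt=sen_tt, green_fraction=green)


def intercepted_par(lai: float, global_rad: float, k: float = EXTINCTION_K) -> float:
    """Daily intercepted PAR (MJ m⁻² day⁻¹) by Beer's law.

    ``PAR_FRACTION * global_rad * (1 - exp(-k * lai))``; bounded above by
    ``PAR_FRACTION * global_rad``.
    """
    if lai < 0 or global_rad < 0:
        raise ValueError("lai and global_rad must be >= 0")
    return PAR_FRACTION * global_rad * (1.0 - math.exp(-k * lai))
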