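"""Layered soil water balance with root extraction and stress factors.

The soil is a cascade of 5-cm layers holding plant-available water up to a
per-layer capacity.  Rain fills layers top-down; excess below the bottom
layer drains away.  On any day the crop can extract only a fraction of each
rooted layer's stored water: 10% at the soil surface declining linearly to
the cultivar's R_u (%) at the current root front.  The daily water-stress
factor is FW = min(1, supply/demand); its mean over the reproductive window
is the drought stress factor (DSF) that reduces grain set.  Transpiration
demand is a Priestley-Taylor-style equilibrium evaporation scaled by the
canopy's intercepted-light fraction; soil evaporation is not modelled (the
available-water-capacity semantics absorb it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SoilProfile", "WaterStressState", "soil_profile",
    "infiltrate_and_drain", "extraction_fractions", "extractable_supply",
    "transpiration_demand", "water_stress_step", "drought_stress_factor",
    "SURFACE_EXTRACTION_PCT", "LAYER_THICKNESS_CM", "BUILTIN_PROFILES",
]

#: Daily extractable fraction at the soil surface (%).
SURFACE_EXTRACTION_PCT = 10.0
#: Thickness of each soil layer (cm).
LAYER_THICKNESS_CM = 5.0
#: Built-in profiles: name -> (total available water capacity mm, depth cm).
BUILTIN_PROFILES = {"rothamsted_210": (210.0, 150.0), "lincoln_270": (270.0, 150.0)}


@dataclass
class SoilProfile:
    """Cascade of equal 5-cm layers of plant-available water."""

    capacity: np.ndarray   # per-layer available water capacity (mm)
    water: np.ndarray      # current available water per layer (mm)
    name: str = ""

    def __post_init__(self) -> None:
        self.capacity = np.asarray(self.capacity, dtype=float)
        self.water = np.asarray(self.water, dtype=float)
        if self.capacity.ndim != 1 or len(self.capacity) == 0:
            raise ValueError("capacity must be a non-empty 1-d array")
        if np.any(self.capacity <= 0):
            raise ValueError("layer capacities must be positive")
        if self.water.shape != self.capacity.shape:
            raise ValueError("water and capacity must have the same shape")
        if np.any(self.water < -1e-12) or np.any(self.water > self.capacity + 1e-9):
            raise ValueError("layer water must lie in [0, capacity]")

    @property
    def n_layers(self) -> int:
        return len(self.capacity)

    @property
    def total_awc(self) -> float:
        return float(self.capacity.sum())

    @property
    def total_water(self) -> float:
        return float(self.water.sum())

    @property
    def max_depth_cm(self) -> float:
        return self.n_layers * LAYER_THICKNESS_CM

    def copy(self) -> "SoilProfile":
        return SoilProfile(self.capacity.copy(), self.water.copy(), self.name)


def soil_profile(name: str, *, full: bool = True) -> SoilProfile:
    """A built-in soil profile (initialized full at sowing by default)."""
    try:
        awc, depth = BUILTIN_PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown soil profile {name!r}; known: {sorted(BUILTIN_PROFILES)}") from None
    n = int(round(depth / LAYER_THICKNESS_CM))
    cap = np.full(n, awc / n)
    return SoilProfile(cap, cap.copy() if full else np.zeros(n), name)


@dataclass
class WaterStressState:
    """Daily supply/demand bookkeeping and the rolling FW record."""

    supply: float = 0.0
    demand: float = 0.0
    fw: float = 1.0                       # min(1, supply/demand), 1 if no demand
    fw_history: list = field(default_factory=list)


def infiltrate_and_drain(profile: SoilProfile, rain: float) -> tuple[SoilProfile, float]:
    """Add rain top-down to a copy of the profile; return (profile, drainage).

    Mass balance holds exactly: rain = Δstorage + drainage.
    """
    if rain < 0:
        raise ValueError(f"rain must be >= 0, got {rain}")
    out = profile.copy()
    remaining = rain
    for i in range(out.n_layers):
        if remaining <= 0:
            break
        room = out.capacity[i] - out.water[i]
        added = min(room, remaining)
        out.water[i] += added
        remaining -= added
    return out, remaining


def extraction_fractions(profile: SoilProfile, root_depth_cm: float,
                         r_u_pct: float) -> np.ndarray:
    """Daily extractable fraction (0-1) per layer for a given root depth.

    Linear decline from ``SURFACE_EXTRACTION_PCT`` % at the surface to
    ``r_u_pct`` % at the root front, evaluated at each rooted layer's top
    depth; zero below the root front.
    """
    if root_depth_cm < 0:
        raise ValueError(f"root depth must be >= 0, got {root_depth_cm}")
    root_depth_cm = min(root_depth_cm, profile.max_depth_cm)
    tops = np.arange(profile.n_layers) * LAYER_THICKNESS_CM
    frac = np.zeros(profile.n_layers)
    rooted = tops < root_depth_cm
    if root_depth_cm > 0 and rooted.any():
        f_surface = SURFACE_EXTRACTION_PCT / 100.0
        f_bottom = r_u_pct / 100.0
        frac[rooted] = f_surface + (f_bottom - f_surface) * tops[rooted] / root_depth_cm
    return np.clip(frac, 0.0, 1.0)


def extractable_supply(profile: SoilProfile, root_depth_cm: float,
                       r_u_pct: float) -> float:
    """Water (mm) the crop can extract today over all rooted layers."""
    frac = extraction_fractions(profile, root_depth_cm, r_u_pct)
    return float(np.sum(profile.water * frac))


# Priestley-Taylor constants.
_PT_ALPHA = 1.26
_PSYCHROMETRIC = 0.066       # kPa K-1
_LATENT_HEAT = 2.45          # MJ kg-1
_NET_RAD_FRACTION = 0.8      # net/global shortwave radiation


def transpiration_demand(global_rad: float, t_mean: float,
                         f_par_intercepted: float) -> float:
    """Daily transpiration demand (mm): equilibrium evaporation × interception.

    A Priestley-Taylor-style estimate: α Δ/(Δ+γ) Rn/λ with Rn taken as a
    fixed fraction of global radiation, multiplied by the canopy's
    intercepted-light fraction.  Zero when radiation or interception is zero;
    increasing in radiation.
    """
    if global_rad < 0 or not 0.0 <= f_par_intercepted <= 1.0:
        raise ValueError("global_rad must be >= 0 and f_par_intercepted in [0, 1]")
    es = 0.6108 * np.exp(17.27 * t_mean / (t_mean + 237.3))
    delta = 4098.0 * es / (t_mean + 237.3) ** 2
    eq_evap = _PT_ALPHA * delta / (delta + _PSYCHROMETRIC) \
        * _NET_RAD_FRACTION * global_rad / _LATENT_HEAT
    return max(0.0, eq_evap) * f_par_intercepted


def water_stress_step(state: WaterStressState, supply: float, demand: float,
                      profile: SoilProfile, root_depth_cm: float,
                      r_u_pct: float) -> tuple[WaterStressState, SoilProfile]:
    """One day of uptake: compute FW and remove the actual uptake.

    FW = 1 if there is no demand, else min(1, supply/demand).  The uptake
    min(supply, demand) is removed from rooted layers proportionally to each
    layer's extractable amount, so no layer is drawn below zero.
    """
    if supply < 0 or demand < 0:
        raise ValueError("supply and demand must be >= 0")
    fw = 1.0 if demand <= 0 else min(1.0, supply / demand)
    out = profile.copy()
    uptake = min(supply, demand)
    if uptake > 0:
        extractable = out.water * extraction_fractions(out, root_depth_cm, r_u_pct)
        total = extractable.sum()
        if total > 0:
            out.water -= uptake * extractable / total
            np.clip(out.water, 0.0, None, out=out.water)
    new_state = WaterStressState(supply=supply, demand=demand, fw=fw,
                                 fw_history=state.fw_history + [fw])
    return new_state, out


def drought_stress_factor(fw_window: "np.ndarray | list") -> float:
    """Drought stress factor: mean FW over the reproductive window, in [0, 1]."""
    fw_window = np.asarray(fw_window, dtype=float)
    if fw_window.size == 0:
        raise ValueError("empty FW window")
    return float(np.clip(fw_window.mean(), 0.0, 1.0))
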