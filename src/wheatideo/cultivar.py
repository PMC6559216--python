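"""Cultivar parameterization for winter wheat.

The 22 parameters describe one cultivar's phenology, canopy, grain formation
and stress responses.  The reference parameterization is the European winter
wheat cv. Claire, a widely grown, consistently high-yielding variety.  A
subset of eight traits (``TRAIT_NAMES``) spans the genetic variation observed
in wheat germplasm and is the search space for ideotype optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields

import numpy as np

__all__ = ["CultivarParams", "CLAIRE", "TRAIT_NAMES", "TRAIT_RANGES"]


@dataclass(frozen=True)
class CultivarParams:
    """Full cultivar description.

    Units follow field convention: thermal times in °C day, leaf areas in
    m² leaf m⁻² soil, rates per day or per °C, grain weight in g.
    """

    p_h: float = 110.0        # phyllochron (°C day per leaf)
    p_p: float = 0.5          # day-length response (leaf h⁻¹ day length)
    tt_sowem: float = 150.0   # thermal time sowing → emergence (°C day)
    tt_anbgf: float = 100.0   # anthesis → beginning of grain fill (°C day)
    tt_bgfegf: float = 650.0  # begin → end of grain fill, a.k.a. G_f (°C day)
    tt_egfmat: float = 200.0  # end of grain fill → harvest maturity (°C day)
    a_max: float = 0.0070     # maximum area of flag leaf (m² m⁻²)
    l_min: float = 8.0        # minimum possible leaf number
    l_max: float = 18.0       # absolute maximum leaf number
    vai: float = 0.0012       # response of vernalisation rate to temperature (day⁻¹ °C⁻¹)
    vbee: float = 0.012       # vernalisation rate at 0 °C (day⁻¹)
    hsgnt: float = 30.0       # heat-stress grain-number reduction threshold (°C)
    hsgnr: float = 0.04       # heat-stress grain-number reduction rate (°C⁻¹)
    dsgnt: float = 0.90       # drought-stress grain-number reduction threshold (-)
    dsgns: float = 0.30       # drought-stress grain-number reduction saturation (-)
    dsgnr_max: float = 0.20   # maximum drought-stress grain-number reduction (-)
    max_gw: float = 0.045     # maximum potential grain weight (g)
    gn_ear: float = 100.0     # grain number per g DM ear (g⁻¹)
    s_g: float = 0.50         # stay-green trait (-)
    r_u: float = 3.0          # rate of root water uptake from the root bottom (%)
    w_sa: float = 0.500       # response of photosynthesis to water stress (-)
    w_ss: float = 1.270       # max acceleration of leaf senescence under water stress (-)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"cultivar parameter {f.name} must be finite, got {v!r}")
        if self.s_g < 0:
            raise ValueError(f"s_g must be >= 0, got {self.s_g}")
        for name in ("p_h", "tt_sowem", "tt_anbgf", "tt_bgfegf", "tt_egfmat",
                     "a_max", "l_min", "l_max", "max_gw", "gn_ear"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cultivar parameter {name} must be positive")
        if self.l_min > self.l_max:
            raise ValueError(f"l_min ({self.l_min}) must not exceed l_max ({self.l_max})")
        if not self.dsgns < self.dsgnt:
            raise ValueError(
                f"dsgns ({self.dsgns}) must be strictly below dsgnt ({self.dsgnt})")

    def with_traits(self, values: "np.ndarray | dict") -> "CultivarParams":
        """Return a copy with the eight optimizable traits replaced.

        ``values`` is either a mapping or an array ordered as ``TRAIT_NAMES``.
        """
        if not isinstance(values, dict):
            values = dict(zip(TRAIT_NAMES, np.asarray(values, dtype=float)))
        unknown = set(values) - set(TRAIT_NAMES)
        if unknown:
            raise ValueError(f"not optimizable traits: {sorted(unknown)}")
        return replace(self, **{k: float(v) for k, v in values.items()})

    def trait_vector(self) -> np.ndarray:
        """The eight optimizable traits, ordered as ``TRAIT_NAMES``."""
        return np.array([getattr(self, n) for n in TRAIT_NAMES], dtype=float)


#: Calibrated parameter set of winter wheat cv. Claire.
CLAIRE = CultivarParams()

#: Optimizable traits, in reporting order: phenology (P_h, P_p, G_f), canopy
#: (A_Max, S_G), root water uptake (R_u) and drought tolerance (W_sa, W_ss).
TRAIT_NAMES = ("p_h", "p_p", "tt_bgfegf", "a_max", "s_g", "r_u", "w_sa", "w_ss")

#: Optimization ranges spanning genetic variation observed in wheat germplasm.
TRAIT_RANGES: dict[str, tuple[float, float]] = {
    "p_h": (70.0, 120.0),
    "p_p": (0.065, 0.900),
    "tt_bgfegf": (500.0, 900.0),
    "a_max": (0.005, 0.010),
    "s_g": (0.0, 1.5),
    "r_u": (1.0, 5.0),
    "w_sa": (0.1, 1.0),
    "w_ss": (1.0, 1.7),
}
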