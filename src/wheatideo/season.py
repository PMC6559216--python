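"""Season orchestration and multi-year ensemble aggregation.

``simulate_season`` runs the daily loop — thermal time, phenology, canopy,
soil water (skipped under irrigation, where the water-stress factor is
pinned to 1), biomass, grain set and grain fill — from a fixed sowing date
to harvest maturity (or a 400-day failsafe).  ``simulate_ensemble`` repeats
it for consecutive sowing years of a continuous weather series and
aggregates yields into mean, SD, CV and the 5/25/50/75/95 percentiles.
Yields are reported in t ha⁻¹ (1 g m⁻² = 0.01 t ha⁻¹).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field

import numpy as np

from dataclasses import fields as _dc_fields

from . import _core
from .cultivar import CultivarParams
from .carbon import co2_rue_factor, RUE_BASE, EAR_BIOMASS_FRACTION
from .canopy import EXTINCTION_K, PAR_FRACTION, FIRST_LEAF_FRACTION, PLANTS_PER_M2
from .phenology import DL_REF_HOURS, FLN_DL_SCALE, ANTHESIS_LAG_PHYLLOCHRONS
from .soil import soil_profile, SURFACE_EXTRACTION_PCT, LAYER_THICKNESS_CM
from .weather import WeatherSeries, MONTH_LENGTHS

__all__ = [
    "SimConfig", "SeasonResult", "EnsembleResult",
    "simulate_season", "simulate_ensemble", "sowing_doy", "doy_to_date",
    "max_seasons",
]

#: Typical sowing dates: 20 October (UK) and 20 April (NZ), as day of year
#: on the 365-day calendar.
SOWING_DOY = {"UK": 293, "NZ": 110}


def sowing_doy(country: str) -> int:
    try:
        return SOWING_DOY[country]
    except KeyError:
        raise ValueError(f"unknown country {country!r}") from None


_MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
_CUM_MONTH = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])


def doy_to_date(doy: int) -> str:
    """Calendar date string ('22-Jun') for a 1-based day of the 365-day year."""
    doy = (int(doy) - 1) % 365 + 1
    month = int(np.searchsorted(_CUM_MONTH, doy - 1, side="right")) - 1
    return f"{doy - _CUM_MONTH[month]}-{_MONTH_ABBR[month]}"


@dataclass(frozen=True)
class SimConfig:
    """Site, management and model-constant configuration for one run."""

    sowing_doy: int = 293                # day of year of sowing
    latitude: float = 51.80              # degrees, signed
    soil: str = "rothamsted_210"         # built-in soil profile id
    water_mode: str = "rainfed"          # 'rainfed' | 'irrigated'
    co2: float = 364.0                   # ppm
    lue_mult: float = 1.0                # light-use-efficiency multiplier
    k: float = EXTINCTION_K
    rue_base: float = RUE_BASE
    ear_fraction: float = EAR_BIOMASS_FRACTION
    anthesis_lag: float = ANTHESIS_LAG_PHYLLOCHRONS
    dl_ref: float = DL_REF_HOURS
    fln_scale: float = FLN_DL_SCALE
    t_base: float = 0.0
    t_opt: float = 10.0                  # temperature-factor saturation (°C)
    dsf_window_tt: float = 300.0         # pre-anthesis DSF window (°C day)
    root_depth0_cm: float = 5.0
    root_rate_cm_per_tt: float = 0.1     # root-front growth per °C day
    failsafe_days: int = 400
    plants_per_m2: float = PLANTS_PER_M2  # shoot density scaling layer areas to LAI

    def __post_init__(self) -> None:
        if self.water_mode not in ("rainfed", "irrigated"):
            raise ValueError(
                f"water_mode must be 'rainfed' or 'irrigated', got {self.water_mode!r}")
        if not 1 <= self.sowing_doy <= 365:
            raise ValueError(f"sowing_doy must be in 1..365, got {self.sowing_doy}")
        for name in ("co2", "lue_mult", "k", "rue_base", "ear_fraction", "dl_ref",
                     "t_opt", "dsf_window_tt", "failsafe_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config constant {name} must be positive")

    @property
    def irrigated(self) -> bool:
        return self.water_mode == "irrigated"

    def hash(self) -> str:
        """Short provenance hash of the configuration."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _cultivar_vector(cv: CultivarParams) -> np.ndarray:
    return np.array([getattr(cv, f.name) for f in _dc_fields(cv)], dtype=float)


def _config_vector(config: SimConfig) -> np.ndarray:
    cf = np.zeros(21)
    cf[_core.C_PLANTS] = config.plants_per_m2
    cf[_core.C_LAT] = config.latitude
    cf[_core.C_IRRIGATED] = 1.0 if config.irrigated else 0.0
    cf[_core.C_CO2F] = co2_rue_factor(config.co2)
    cf[_core.C_LUE] = config.lue_mult
    cf[_core.C_K] = config.k
    cf[_core.C_RUE] = config.rue_base
    cf[_core.C_EARFRAC] = config.ear_fraction
    cf[_core.C_ANTHLAG] = config.anthesis_lag
    cf[_core.C_DLREF] = config.dl_ref
    cf[_core.C_FLNSCALE] = config.fln_scale
    cf[_core.C_TBASE] = config.t_base
    cf[_core.C_DSFWIN] = config.dsf_window_tt
    cf[_core.C_ROOT0] = config.root_depth0_cm
    cf[_core.C_ROOTRATE] = config.root_rate_cm_per_tt
    cf[_core.C_FAILSAFE] = config.failsafe_days
    cf[_core.C_TOPT] = config.t_opt
    cf[_core.C_FSURF] = SURFACE_EXTRACTION_PCT / 100.0
    cf[_core.C_LAYERTHICK] = LAYER_THICKNESS_CM
    cf[_core.C_PARFRAC] = PAR_FRACTION
    cf[_core.C_LEAF1FRAC] = FIRST_LEAF_FRACTION
    return cf


@dataclass(frozen=True)
class SeasonResult:
    """Outputs of one simulated season."""

    yield_t_ha: float
    biomass_t_ha: float
    hi: float
    emergence_das: int
    anthesis_das: int
    begin_gf_das: int
    end_gf_das: int
    maturity_das: int
    grain_fill_days: int
    lai_anthesis: float
    cum_intercepted_rad_mj: float     # total solar accounting
    cum_intercepted_par_mj: float
    dsf: float
    heat_reduction: float
    drought_reduction: float
    fln: float
    anthesis_biomass_g_m2: float
    grain_number_m2: float
    failed: bool
    sowing_doy: int
    anthesis_date: str
    maturity_date: str
    # season water books (mm)
    rain_mm: float
    drainage_mm: float
    uptake_mm: float
    soil_water_initial_mm: float
    soil_water_final_mm: float


def simulate_season(cultivar: CultivarParams, weather: WeatherSeries,
                    sowing_year_index: int, config: SimConfig) -> SeasonResult:
    """Simulate one season sown in ``sowing_year_index`` of the series.

    Deterministic given its inputs.  A season that never reaches anthesis
    within the failsafe window is returned flagged with zero yield rather
    than raising.
    """
    start = sowing_year_index * 365 + config.sowing_doy - 1
    if start < 0 or start + config.failsafe_days > len(weather):
        raise ValueError(
            f"weather too short: need {config.failsafe_days} days from sowing "
            f"(index {start}), series has {len(weather)} days")
    sl = slice(start, start + config.failsafe_days)
    profile = soil_profile(config.soil)
    w0 = profile.total_water
    out = _core.season_core(
        np.ascontiguousarray(weather.tmin[sl]),
        np.ascontiguousarray(weather.tmax[sl]),
        np.ascontiguousarray(weather.rain[sl]),
        np.ascontiguousarray(weather.rad[sl]),
        config.sowing_doy,
        _cultivar_vector(cultivar),
        _config_vector(config),
        profile.capacity,
        profile.water,
    )
    o = _core
    anth = int(out[o.O_ANTHESIS])
    mat = int(out[o.O_MATURITY])
    bgf, egf = int(out[o.O_BGF]), int(out[o.O_EGF])
    return SeasonResult(
        yield_t_ha=0.01 * out[o.O_YIELD],
        biomass_t_ha=0.01 * out[o.O_BIOMASS],
        hi=out[o.O_HI],
        emergence_das=int(out[o.O_EMERGENCE]),
        anthesis_das=anth,
        begin_gf_das=bgf,
        end_gf_das=egf,
        maturity_das=mat,
        grain_fill_days=(egf - bgf) if (egf >= 0 and bgf >= 0) else -1,
        lai_anthesis=out[o.O_LAI_ANTH],
        cum_intercepted_rad_mj=out[o.O_CUM_RAD],
        cum_intercepted_par_mj=out[o.O_CUM_PAR],
        dsf=out[o.O_DSF],
        heat_reduction=out[o.O_HEAT_RED],
        drought_reduction=out[o.O_DROUGHT_RED],
        fln=out[o.O_FLN],
        anthesis_biomass_g_m2=out[o.O_ANTH_BIOMASS],
        grain_number_m2=out[o.O_GRAIN_NUMBER],
        failed=bool(out[o.O_FAILED]),
        sowing_doy=config.sowing_doy,
        anthesis_date=doy_to_date(config.sowing_doy + anth) if anth >= 0 else "",
        maturity_date=doy_to_date(config.sowing_doy + mat) if mat >= 0 else "",
        rain_mm=out[o.O_RAIN_IN],
        drainage_mm=out[o.O_DRAINAGE],
        uptake_mm=out[o.O_UPTAKE],
        soil_water_initial_mm=w0,
        soil_water_final_mm=profile.total_water,
    )


def max_seasons(weather: WeatherSeries, config: SimConfig) -> int:
    """Number of complete seasons the series supports for this sowing date."""
    usable = len(weather) - (config.sowing_doy - 1) - config.failsafe_days
    return max(0, usable // 365 + 1)


@dataclass(frozen=True)
class EnsembleResult:
    """Aggregate of one season per sowing year."""

    seasons: tuple[SeasonResult, ...]
    mean_yield: float
    sd_yield: float
    cv_pct: float
    mean_hi: float
    yield_percentiles: dict = field(default_factory=dict)

    @property
    def yields(self) -> np.ndarray:
        return np.array([s.yield_t_ha for s in self.seasons])

    def percentiles(self, attr: str, probs=(5, 25, 50, 75, 95)) -> dict:
        """Linear-interpolation percentiles of any per-season output."""
        vals = np.array([getattr(s, attr) for s in self.seasons], dtype=float)
        return {int(p): float(np.percentile(vals, p)) for p in probs}

    def mean(self, attr: str) -> float:
        return float(np.mean([getattr(s, attr) for s in self.seasons]))


def simulate_ensemble(cultivar: CultivarParams, weather: WeatherSeries,
                      config: SimConfig, n_seasons: int | None = None) -> EnsembleResult:
    """Simulate consecutive sowing years and aggregate.

    ``n_seasons`` defaults to every season the series can hold; at least two
    are required.  CV is 100 × SD/mean with the sample (n−1) SD.
    """
    avail = max_seasons(weather, config)
    if n_seasons is None:
        n_seasons = avail
    if n_seasons > avail:
        raise ValueError(f"series supports only {avail} seasons, asked {n_seasons}")
    if n_seasons < 2:
        raise ValueError("an ensemble needs at least 2 seasons")
    seasons = tuple(simulate_season(cultivar, weather, i, config)
                    for i in range(n_seasons))
    yields = np.array([s.yield_t_ha for s in seasons])
    mean = float(yields.mean())
    sd = float(yields.std(ddof=1))
    return EnsembleResult(
        seasons=seasons,
        mean_yield=mean,
        sd_yield=sd,
        cv_pct=100.0 * sd / mean if mean > 0 else float("inf"),
        mean_hi=float(np.mean([s.hi for s in seasons])),
        yield_percentiles={int(p): float(np.percentile(yields, p))
                           for p in (5, 25, 50, 75, 95)},
    )
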