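"""Stochastic daily weather generation and climate-scenario morphing.

A parametric single-site generator produces continuous multi-year daily
series of minimum/maximum temperature, precipitation and global radiation
from twelve sets of monthly statistics:

* precipitation occurrence follows a first-order two-state Markov chain
  (wet-after-wet and wet-after-dry probabilities), wet-day amounts are
  gamma distributed;
* daily temperatures are the monthly means plus an independent Gaussian
  deviation shared by Tmin and Tmax (which preserves Tmax ≥ Tmin);
* radiation is Gaussian around a wet- or dry-day mean, truncated at zero.

Years are 365 days long (no leap days) and series are continuous across
year boundaries, so growing seasons spanning two calendar years are
supported.  Climate-change scenarios are applied by "morphing" the monthly
statistics: additive temperature offsets, multiplicative precipitation and
radiation factors, and a new CO2 concentration.

Six built-in sites cover major wheat-growing regions of the United Kingdom
(Edinburgh ED, Leeds LE, Rothamsted RR) and New Zealand (Gore GO, Lincoln
LI, Pukekohe PU); their monthly statistics are sinusoidal seasonal shapes
(hemisphere-aware phase) fitted so the long-run annual summaries match the
sites' observed 1980-2010 normals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyClimateNormals", "SiteClimateParams", "ClimateScenario",
    "WeatherSeries", "generate_series", "apply_scenario", "summarize_series",
    "site_params", "scenario_2050", "SITE_INFO",
    "read_weather_csv", "write_weather_csv",
    "MONTH_LENGTHS", "MONTH_OF_DOY",
]

#: 365-day calendar (no leap years).
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
#: Month index (1-12) for each day of year (1-based doy -> MONTH_OF_DOY[doy-1]).
MONTH_OF_DOY = np.repeat(np.arange(1, 13), MONTH_LENGTHS)


@dataclass(frozen=True)
class MonthlyClimateNormals:
    """Generator statistics for one calendar month."""

    month: int                 # 1-12
    tmin_mean: float           # °C
    tmax_mean: float           # °C
    t_sd: float                # between-day SD of the shared deviation (°C)
    p_wet_wet: float           # P(wet | previous day wet)
    p_wet_dry: float           # P(wet | previous day dry)
    rain_shape: float          # gamma shape of wet-day amounts (>0)
    rain_scale: float          # gamma scale of wet-day amounts (mm, >0)
    rad_dry: float             # mean global radiation on dry days (MJ m-2 day-1)
    rad_wet: float             # mean global radiation on wet days (MJ m-2 day-1)
    rad_sd: float              # between-day SD of radiation (MJ m-2 day-1)

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")
        for name in ("p_wet_wet", "p_wet_dry"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("t_sd", "rad_sd", "rad_dry", "rad_wet"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rain_shape", "rain_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tmax_mean < self.tmin_mean:
            raise ValueError(
                f"tmax_mean ({self.tmax_mean}) below tmin_mean ({self.tmin_mean}) "
                f"in month {self.month}")

    @property
    def p_wet_stationary(self) -> float:
        """Stationary wet-day probability of the two-state Markov chain."""
        denom = 1.0 + self.p_wet_dry - self.p_wet_wet
        return self.p_wet_dry / denom if denom > 0 else 1.0


@dataclass(frozen=True)
class SiteClimateParams:
    """A site: latitude, CO2 and twelve monthly normals."""

    site_id: str
    latitude: float                  # degrees, signed (south negative)
    months: tuple[MonthlyClimateNormals, ...]
    co2: float = 364.0               # ppm

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude must be in [-90, 90], got {self.latitude}")
        if self.co2 <= 0:
            raise ValueError(f"co2 must be > 0, got {self.co2}")
        if len(self.months) != 12 or [m.month for m in self.months] != list(range(1, 13)):
            raise ValueError("months must hold normals for months 1..12 in order")


@dataclass(frozen=True)
class ClimateScenario:
    """Monthly morphing deltas plus a target CO2 concentration.

    Scalars are broadcast to all twelve months.
    """

    dt: tuple[float, ...]            # additive temperature offset (°C), 12 values
    precip_mult: tuple[float, ...]   # multiplier on gamma scale (>= 0)
    rad_mult: tuple[float, ...]      # multiplier on radiation means (>= 0)
    co2: float                       # ppm
    lue_mult: float = 1.0            # light-use-efficiency multiplier

    def __post_init__(self) -> None:
        for name in ("dt", "precip_mult", "rad_mult"):
            v = getattr(self, name)
            if np.isscalar(v):
                object.__setattr__(self, name, (float(v),) * 12)
            elif len(v) != 12:
                raise ValueError(f"{name} must be a scalar or 12 values")
        for name in ("precip_mult", "rad_mult"):
            if min(getattr(self, name)) < 0:
                raise ValueError(f"{name} values must be >= 0")
        if self.co2 <= 0:
            raise ValueError(f"co2 must be > 0, got {self.co2}")


@dataclass(frozen=True)
class WeatherSeries:
    """Continuous daily weather record (consecutive 365-day years)."""

    year: np.ndarray     # 0-based year index per day
    doy: np.ndarray      # day of year, 1-based
    tmin: np.ndarray     # °C
    tmax: np.ndarray     # °C
    rain: np.ndarray     # mm
    rad: np.ndarray      # MJ m-2 day-1
    seed: int | None = None
    site_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.doy)
        for name in ("year", "tmin", "tmax", "rain", "rad"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} has wrong length")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax below tmin on some day")
        if np.any(self.rain < 0):
            raise ValueError("negative precipitation")
        if np.any(self.rad < 0):
            raise ValueError("negative radiation")
        abs_day = self.year * 365 + self.doy - 1
        if n and np.any(np.diff(abs_day) != 1):
            raise ValueError("dates are not strictly consecutive")

    def __len__(self) -> int:
        return len(self.doy)

    @property
    def n_years(self) -> int:
        return len(self) // 365

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.year, "doy": self.doy,
            "tmin_c": self.tmin, "tmax_c": self.tmax,
            "rain_mm": self.rain, "rad_mj": self.rad,
        })


def _monthly_arrays(params: SiteClimateParams) -> dict[str, np.ndarray]:
    get = lambda name: np.array([getattr(m, name) for m in params.months])
    return {name: get(name) for name in (
        "tmin_mean", "tmax_mean", "t_sd", "p_wet_wet", "p_wet_dry",
        "rain_shape", "rain_scale", "rad_dry", "rad_wet", "rad_sd")}


def generate_series(params: SiteClimateParams, n_years: int, seed: int) -> WeatherSeries:
    """Generate ``n_years`` of daily weather for a site.

    The same ``(params, n_years, seed)`` always yields the identical series.
    Long-run monthly statistics converge to the parameterized normals.
    """
    if not isinstance(n_years, (int, np.integer)) or n_years < 1:
        raise ValueError(f"n_years must be a positive integer, got {n_years!r}")
    rng = np.random.default_rng(seed)
    n_days = int(n_years) * 365
    doy = np.tile(np.arange(1, 366), n_years)
    year = np.repeat(np.arange(n_years), 365)
    mi = MONTH_OF_DOY[doy - 1] - 1       # 0-based month index per day
    p = _monthly_arrays(params)

    # Markov-chain precipitation occurrence.
    u = rng.random(n_days)
    pww, pwd = p["p_wet_wet"][mi], p["p_wet_dry"][mi]
    wet = np.empty(n_days, dtype=bool)
    m0 = params.months[mi[0]]
    state = u[0] < m0.p_wet_stationary
    wet[0] = state
    pww_l, pwd_l, u_l = pww.tolist(), pwd.tolist(), u.tolist()
    wet_l = wet.tolist()
    for t in range(1, n_days):
        state = u_l[t] < (pww_l[t] if state else pwd_l[t])
        wet_l[t] = state
    wet = np.array(wet_l, dtype=bool)

    # Wet-day amounts: gamma with monthly shape/scale.
    rain = np.zeros(n_days)
    if wet.any():
        rain[wet] = rng.gamma(p["rain_shape"][mi][wet], p["rain_scale"][mi][wet])

    # Temperature: monthly means plus a shared Gaussian daily deviation.
    z = rng.standard_normal(n_days)
    tmin = p["tmin_mean"][mi] + p["t_sd"][mi] * z
    tmax = p["tmax_mean"][mi] + p["t_sd"][mi] * z
    tmax = np.maximum(tmax, tmin)

    # Radiation conditioned on wet/dry status, truncated at zero.
    rad_mean = np.where(wet, p["rad_wet"][mi], p["rad_dry"][mi])
    rad = np.maximum(0.0, rad_mean + p["rad_sd"][mi] * rng.standard_normal(n_days))

    return WeatherSeries(year=year, doy=doy, tmin=tmin, tmax=tmax,
                         rain=rain, rad=rad, seed=int(seed), site_id=params.site_id)


def apply_scenario(params: SiteClimateParams, scenario: ClimateScenario) -> SiteClimateParams:
    """Morph site statistics with a climate scenario; the input is unmodified.

    Temperature means are shifted by the monthly offset, the precipitation
    gamma scale and both radiation means are multiplied by the monthly
    factors, and CO2 is replaced.
    """
    months = tuple(
        replace(
            m,
            tmin_mean=m.tmin_mean + scenario.dt[i],
            tmax_mean=m.tmax_mean + scenario.dt[i],
            rain_scale=m.rain_scale * scenario.precip_mult[i]
            if scenario.precip_mult[i] > 0 else 1e-12,
            p_wet_wet=m.p_wet_wet if scenario.precip_mult[i] > 0 else 0.0,
            p_wet_dry=m.p_wet_dry if scenario.precip_mult[i] > 0 else 0.0,
            rad_dry=m.rad_dry * scenario.rad_mult[i],
            rad_wet=m.rad_wet * scenario.rad_mult[i],
        )
        for i, m in enumerate(params.months)
    )
    return replace(params, months=months, co2=scenario.co2)


def summarize_series(series: WeatherSeries) -> dict[str, float]:
    """Whole-series climate summary.

    Returns annual mean air temperature (°C, mean of the daily Tmin/Tmax
    midpoint), mean annual precipitation total (mm yr⁻¹) and mean daily
    global radiation (MJ m⁻² day⁻¹).
    """
    if len(series) == 0:
        raise ValueError("cannot summarize an empty series")
    return {
        "t_mean_c": float(np.mean((series.tmin + series.tmax) / 2.0)),
        "precip_mm_yr": float(np.sum(series.rain) / (len(series) / 365.0)),
        "rad_mj_day": float(np.mean(series.rad)),
    }


# ---------------------------------------------------------------------------
# Built-in sites (annual normals for 1980-2010) and the 2050 scenario.

#: site id -> (name, country, latitude, annual mean T °C, annual precip mm,
#:             mean daily global radiation MJ m-2 day-1)
SITE_INFO: dict[str, tuple[str, str, float, float, float, float]] = {
    "ED": ("Edinburgh", "UK", 55.94, 8.6, 717, 8.7),
    "LE": ("Leeds", "UK", 54.30, 9.5, 626, 8.6),
    "RR": ("Rothamsted", "UK", 51.80, 9.8, 700, 9.8),
    "GO": ("Gore", "NZ", -46.12, 9.8, 976, 12.4),
    "LI": ("Lincoln", "NZ", -43.70, 11.6, 596, 13.6),
    "PU": ("Pukekohe", "NZ", -37.21, 14.5, 1296, 14.0),
}

# Seasonal-shape constants for fitting monthly normals to annual values.
_COUNTRY_SHAPE = {
    # (temp amplitude °C, radiation relative amplitude, warm-peak month)
    "UK": (5.5, 0.85, 7.0),
    "NZ": (4.5, 0.75, 1.0),
}
_DIURNAL_HALF_RANGE = 4.0   # Tmin/Tmax = monthly mean -/+ this (°C)
_T_SD = 2.0                 # between-day temperature SD (°C)
_P_WW, _P_WD = 0.65, 0.35   # wet-after-wet / wet-after-dry probabilities
_RAIN_SHAPE = 0.8           # gamma shape of wet-day amounts
_RAD_SD_FRAC = 0.20         # radiation SD as fraction of the monthly mean
_RAD_DRY_FACTOR = 1.1       # dry-day radiation relative to the monthly mean


def site_params(site_id: str, co2: float = 364.0) -> SiteClimateParams:
    """Built-in parameterization of one of the six study sites.

    Monthly statistics follow sinusoidal seasonality (phase flipped between
    hemispheres) fitted so that the generated long-run annual mean
    temperature, precipitation total and mean radiation match the site's
    observed normals; monthly detail beyond that is a modelling choice.
    """
    try:
        name, country, lat, t_ann, p_ann, r_ann = SITE_INFO[site_id]
    except KeyError:
        raise ValueError(f"unknown site {site_id!r}; known: {sorted(SITE_INFO)}") from None
    t_amp, r_amp, peak = _COUNTRY_SHAPE[country]
    pi_wet = _P_WD / (1.0 + _P_WD - _P_WW)  # stationary wet probability
    rain_scale = (p_ann / 365.0) / (pi_wet * _RAIN_SHAPE)
    months = []
    for m in range(1, 13):
        c = np.cos(2.0 * np.pi * (m - peak) / 12.0)
        t_mean = t_ann + t_amp * c
        r_mean = max(0.5, r_ann * (1.0 + r_amp * c))
        # Split the monthly mean into dry/wet-day means preserving the mixture.
        rad_dry = _RAD_DRY_FACTOR * r_mean
        rad_wet = (r_mean - (1.0 - pi_wet) * rad_dry) / pi_wet
        months.append(MonthlyClimateNormals(
            month=m,
            tmin_mean=t_mean - _DIURNAL_HALF_RANGE,
            tmax_mean=t_mean + _DIURNAL_HALF_RANGE,
            t_sd=_T_SD,
            p_wet_wet=_P_WW, p_wet_dry=_P_WD,
            rain_shape=_RAIN_SHAPE, rain_scale=rain_scale,
            rad_dry=rad_dry, rad_wet=max(0.0, rad_wet),
            rad_sd=_RAD_SD_FRAC * r_mean,
        ))
    return SiteClimateParams(site_id=site_id, latitude=lat,
                             months=tuple(months), co2=co2)


def scenario_2050(country: str, lue_mult: float = 1.0) -> ClimateScenario:
    """The 2050 high-emission scenario as country-level morphing deltas.

    Warming of +2.1 °C (UK) / +1.9 °C (NZ), radiation +6.7% / +1.1%, a small
    (2%) precipitation decrease, and CO2 raised from 364 to 541 ppm.  For
    ideotype design a 10% light-use-efficiency gain is assumed
    (``lue_mult=1.10``).
    """
    if country == "UK":
        return ClimateScenario(dt=2.1, precip_mult=0.98, rad_mult=1.067,
                               co2=541.0, lue_mult=lue_mult)
    if country == "NZ":
        return ClimateScenario(dt=1.9, precip_mult=0.98, rad_mult=1.011,
                               co2=541.0, lue_mult=lue_mult)
    raise ValueError(f"unknown country {country!r}; expected 'UK' or 'NZ'")


# ---------------------------------------------------------------------------
# CSV interface: one row per day, header mandatory.

_CSV_COLS = ["year", "doy", "tmin_c", "tmax_c", "rain_mm", "rad_mj"]


def write_weather_csv(series: WeatherSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_weather_csv(path) -> WeatherSeries:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"weather CSV missing columns: {missing}")
    return WeatherSeries(
        year=df["year"].to_numpy(int), doy=df["doy"].to_numpy(int),
        tmin=df["tmin_c"].to_numpy(float), tmax=df["tmax_c"].to_numpy(float),
        rain=df["rain_mm"].to_numpy(float), rad=df["rad_mj"].to_numpy(float),
    )
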