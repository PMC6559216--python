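"""End-to-end experimental design: current cultivar vs optimized ideotypes.

Four treatments per site reproduce the study design:

* ``CL_Base`` — cv. Claire, rainfed, baseline climate (CO2 364 ppm);
* ``CL_2050`` — cv. Claire, rainfed, 2050 climate (CO2 541 ppm, country
  warming/radiation/precipitation deltas);
* ``IW_2050`` — ideotype optimized by EASA for the rainfed 2050 climate
  (with the assumed 10% light-use-efficiency gain);
* ``IP_2050`` — ideotype optimized for the irrigated (potential) 2050
  climate.

Outputs are per-season CSV tables and a JSON summary per site/treatment,
each carrying the seed and a configuration hash for provenance.  Report
tables aggregate to country level as unweighted means over each country's
three sites, with percent differences rounded to integer percent.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cultivar import CLAIRE, CultivarParams, TRAIT_NAMES
from .easa import OptimizationSpec, run_easa, make_yield_evaluator
from .season import SimConfig, EnsembleResult, simulate_ensemble, sowing_doy
from .weather import (SITE_INFO, site_params, scenario_2050, apply_scenario,
                      generate_series, summarize_series)

__all__ = [
    "ExperimentConfig", "run_experiment", "percent_difference", "make_report",
    "site_sim_config", "load_config", "save_config", "TREATMENTS",
]

logger = logging.getLogger("wheatideo")

TREATMENTS = ("CL_Base", "CL_2050", "IW_2050", "IP_2050")

_COUNTRY_SOIL = {"UK": "rothamsted_210", "NZ": "lincoln_270"}
#: Light-use-efficiency gain assumed for ideotype design under 2050 climate.
LUE_2050 = 1.10


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of a full (or reduced) experiment."""

    sites: tuple = tuple(SITE_INFO)
    treatments: tuple = TREATMENTS
    n_seasons: int = 100          # ensemble seasons per treatment
    seed: int = 12345
    outdir: str = "results/experiment"
    # optimizer settings (EASA)
    starts: int = 8
    offspring: int = 16
    max_steps: int = 200
    patience: int = 20

    def __post_init__(self) -> None:
        unknown = set(self.sites) - set(SITE_INFO)
        if unknown:
            raise ValueError(f"unknown sites: {sorted(unknown)}")
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatments: {sorted(unknown)}")
        if self.n_seasons < 2:
            raise ValueError("n_seasons must be >= 2")


def site_sim_config(site_id: str, *, water_mode: str = "rainfed",
                    co2: float = 364.0, lue_mult: float = 1.0) -> SimConfig:
    """Simulation configuration for a built-in site."""
    name, country, lat, *_ = SITE_INFO[site_id]
    return SimConfig(sowing_doy=sowing_doy(country), latitude=lat,
                     soil=_COUNTRY_SOIL[country], water_mode=water_mode,
                     co2=co2, lue_mult=lue_mult)


def percent_difference(a: float, b: float) -> float:
    """Percent difference of ``a`` relative to ``b``: 100 × (a − b)/b."""
    if b == 0:
        raise ValueError("zero baseline in percent difference")
    return 100.0 * (a - b) / b


def _ensemble_summary(ens: EnsembleResult, config: SimConfig, seed: int) -> dict:
    anth = [s.anthesis_das for s in ens.seasons if s.anthesis_das >= 0]
    mat = [s.maturity_das for s in ens.seasons if s.maturity_das >= 0]
    return {
        "mean_yield_t_ha": round(ens.mean_yield, 3),
        "sd_yield_t_ha": round(ens.sd_yield, 3),
        "cv_pct": round(ens.cv_pct, 2),
        "mean_hi": round(ens.mean_hi, 4),
        "yield_percentiles": {k: round(v, 3) for k, v in ens.yield_percentiles.items()},
        "mean_lai_anthesis": round(ens.mean("lai_anthesis"), 3),
        "mean_grain_fill_days": round(ens.mean("grain_fill_days"), 2),
        "mean_cum_intercepted_rad_mj": round(ens.mean("cum_intercepted_rad_mj"), 1),
        "mean_anthesis_das": round(float(np.mean(anth)), 1) if anth else None,
        "sd_anthesis_das": round(float(np.std(anth, ddof=1)), 1) if len(anth) > 1 else None,
        "mean_maturity_das": round(float(np.mean(mat)), 1) if mat else None,
        "sd_maturity_das": round(float(np.std(mat, ddof=1)), 1) if len(mat) > 1 else None,
        "n_seasons": len(ens.seasons),
        "seed": seed,
        "config_hash": config.hash(),
    }


def _seasons_frame(ens: EnsembleResult) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in ens.seasons])


def run_experiment(config: ExperimentConfig) -> dict:
    """Run every requested treatment at every requested site.

    Returns the nested result dict (site → treatment → summary) and writes
    per-season CSVs plus a JSON summary under ``config.outdir``.  Idempotent
    for fixed seeds.  A failing stage raises with the stage label; outputs
    of completed stages are retained on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    site_seeds = {site: s for site, s in zip(config.sites, ss.spawn(len(config.sites)))}
    results: dict = {}

    for site in config.sites:
        country = SITE_INFO[site][1]
        base_seed, s2050_seed, opt_w_seed, opt_p_seed = \
            site_seeds[site].spawn(4)
        n_weather_years = config.n_seasons + 2
        results[site] = {}
        stage = f"{site}/weather"
        try:
            t0 = time.perf_counter()
            params_base = site_params(site)
            weather_base = generate_series(
                params_base, n_weather_years, _to_int_seed(base_seed))
            params_2050 = apply_scenario(params_base, scenario_2050(country))
            weather_2050 = generate_series(
                params_2050, n_weather_years, _to_int_seed(s2050_seed))
            logger.info("%s: weather generated in %.1fs", stage,
                        time.perf_counter() - t0)

            for treatment in config.treatments:
                stage = f"{site}/{treatment}"
                t0 = time.perf_counter()
                if treatment == "CL_Base":
                    cfg = site_sim_config(site, co2=364.0)
                    ens = simulate_ensemble(CLAIRE, weather_base, cfg,
                                            n_seasons=config.n_seasons)
                    summary = _ensemble_summary(ens, cfg, config.seed)
                elif treatment == "CL_2050":
                    cfg = site_sim_config(site, co2=541.0)
                    ens = simulate_ensemble(CLAIRE, weather_2050, cfg,
                                            n_seasons=config.n_seasons)
                    summary = _ensemble_summary(ens, cfg, config.seed)
                else:
                    water = "rainfed" if treatment == "IW_2050" else "irrigated"
                    opt_seed = opt_w_seed if treatment == "IW_2050" else opt_p_seed
                    cfg = site_sim_config(site, water_mode=water, co2=541.0,
                                          lue_mult=LUE_2050)
                    spec = OptimizationSpec(starts=config.starts,
                                            offspring=config.offspring,
                                            max_steps=config.max_steps,
                                            patience=config.patience)
                    evaluator = make_yield_evaluator(
                        weather_2050, cfg, n_seasons=config.n_seasons)
                    opt = run_easa(spec, evaluator, opt_seed)
                    if not opt.succeeded:
                        raise RuntimeError("no feasible ideotype found")
                    ideotype = opt.best_cultivar(spec)
                    ens = simulate_ensemble(ideotype, weather_2050, cfg,
                                            n_seasons=config.n_seasons)
                    summary = _ensemble_summary(ens, cfg, config.seed)
                    summary["traits"] = {n: float(v) for n, v in
                                         zip(spec.names, opt.best.values)}
                    summary["n_evaluations"] = opt.n_evaluations
                _seasons_frame(ens).to_csv(outdir / f"{site}_{treatment}_seasons.csv",
                                           index=False)
                results[site][treatment] = summary
                logger.info("%s: done in %.1fs (mean yield %.2f t/ha)", stage,
                            time.perf_counter() - t0, summary["mean_yield_t_ha"])
            results[site]["climate"] = {
                "baseline": {k: round(v, 2) for k, v in
                             summarize_series(weather_base).items()},
                "2050": {k: round(v, 2) for k, v in
                         summarize_series(weather_2050).items()},
            }
        except Exception as exc:
            raise RuntimeError(f"experiment stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump({"seed": config.seed, "results": results}, fh, indent=2)
    return results


def make_report(results: dict) -> dict[str, pd.DataFrame]:
    """Report tables from ``run_experiment`` results.

    Returns site-level means, unweighted country means, percent yield gains
    over the baselines, the ideotype trait table and phenology dates.
    Raises on empty or incomplete results.
    """
    if not results:
        raise ValueError("no data: empty results")
    sites = [s for s in results if s in SITE_INFO]

    rows = []
    for site in sites:
        for treatment in TREATMENTS:
            if treatment not in results[site]:
                continue
            r = results[site][treatment]
            rows.append({
                "site": site, "country": SITE_INFO[site][1], "treatment": treatment,
                "mean_yield_t_ha": round(r["mean_yield_t_ha"], 1),
                "cv_pct": round(r["cv_pct"], 1),
                "mean_hi": round(r["mean_hi"], 2),
                "mean_lai_anthesis": round(r["mean_lai_anthesis"], 1),
                "mean_grain_fill_days": round(r["mean_grain_fill_days"], 0),
            })
    if not rows:
        raise ValueError("no data: no treatment summaries present")
    site_means = pd.DataFrame(rows)

    country_means = (site_means
                     .groupby(["country", "treatment"], as_index=False)
                     .agg({"mean_yield_t_ha": "mean", "mean_hi": "mean",
                           "mean_lai_anthesis": "mean",
                           "mean_grain_fill_days": "mean"})
                     .round({"mean_yield_t_ha": 1, "mean_hi": 2,
                             "mean_lai_anthesis": 1, "mean_grain_fill_days": 0}))

    gains = []
    for _, row in country_means.iterrows():
        if row["treatment"] == "CL_Base":
            continue
        base = country_means[(country_means.country == row["country"])
                             & (country_means.treatment == "CL_Base")]
        if base.empty:
            continue
        b = float(base["mean_yield_t_ha"].iloc[0])
        gains.append({
            "country": row["country"], "treatment": row["treatment"],
            "gain_over_CL_Base_pct": int(round(percent_difference(
                float(row["mean_yield_t_ha"]), b))),
        })

    traits = []
    for site in sites:
        for treatment in ("IW_2050", "IP_2050"):
            r = results[site].get(treatment, {})
            if "traits" in r:
                traits.append({"site": site, "country": SITE_INFO[site][1],
                               "treatment": treatment,
                               **{n: r["traits"][n] for n in TRAIT_NAMES}})

    dates = []
    for site in sites:
        for treatment in TREATMENTS:
            r = results[site].get(treatment)
            if r and r.get("mean_anthesis_das") is not None:
                dates.append({
                    "site": site, "treatment": treatment,
                    "anthesis_das": r["mean_anthesis_das"],
                    "anthesis_sd": r["sd_anthesis_das"],
                    "maturity_das": r["mean_maturity_das"],
                    "maturity_sd": r["sd_maturity_das"],
                })

    return {
        "site_means": site_means,
        "country_means": country_means,
        "percent_gains": pd.DataFrame(gains),
        "ideotype_traits": pd.DataFrame(traits),
        "phenology_dates": pd.DataFrame(dates),
    }


def _to_int_seed(ss: np.random.SeedSequence) -> int:
    """A plain integer seed (< 2^31) derived from a SeedSequence."""
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("sites", "treatments"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ExperimentConfig(**raw)


def save_config(config: ExperimentConfig, path) -> None:
    d = asdict(config)
    d["sites"] = list(d["sites"])
    d["treatments"] = list(d["treatments"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
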