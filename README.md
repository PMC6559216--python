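# wheatideo

Designing wheat ideotypes — virtual idealized cultivars — for mid-century
climate. The package is aimed at crop modellers and breeding strategists who
want to ask: *which combination of cultivar trait values maximizes stable
grain yield at a given site under a 2050 climate, rainfed or irrigated?*

It combines three components:

1. **A stochastic weather generator** producing seeded, multi-year daily
   series (Tmin, Tmax, precipitation, global radiation) from monthly
   statistics: first-order two-state Markov-chain rainfall occurrence with
   gamma-distributed wet-day amounts, Gaussian temperature deviations around
   monthly means, and radiation conditioned on wet/dry status. Built-in
   parameterizations cover six wheat-growing sites — Edinburgh (ED), Leeds
   (LE) and Rothamsted (RR) in the UK; Gore (GO), Lincoln (LI) and Pukekohe
   (PU) in New Zealand — and a "2050" morphing scenario (UK: +2.1 °C,
   radiation ×1.067; NZ: +1.9 °C, ×1.011; precipitation −2%; CO₂ 364 → 541 ppm).

2. **A process-based daily wheat growth model.** Phenology is thermal-time
   driven: leaves appear once per phyllochron *P_h*; the final leaf number is
   fixed at vernalization saturation and decreases with day length at the
   rate *P_p*; anthesis, the grain-fill window *G_f* and maturity follow in
   fixed thermal-time increments. The canopy is a stack of leaf layers
   (flag-leaf area *A_Max*), senescing after anthesis with a stay-green delay
   *S_G*, fully senesced at the end of grain fill. Daily biomass is
   intercepted PAR × radiation use efficiency,

   ΔB = 0.5 · R_g · (1 − e^(−k·LAI)) · RUE · f_CO₂ · f_LUE · f_T · (1 − W_sa(1 − FW)),

   with f_CO₂ = 1 + 0.30 (CO₂ − 338)/338. Soil water is a cascade of 5-cm
   layers (210 mm available capacity in the UK profile, 270 mm in NZ); daily
   extractable water declines from 10% at the surface to *R_u* % at the root
   front, and the stress factor FW = min(1, supply/demand) feeds drought
   (DSF) and heat stress reductions of grain number around anthesis. Grain
   fill receives new assimilate plus a labile pool of 25% of anthesis
   biomass, capped at grain number × 0.045 g.

3. **EASA, an evolutionary search with self-adaptation** — a (1+16)
   evolution strategy whose per-trait mutation step sizes are inherited and
   co-evolve with the trait values (log-normal step mutation, τ = 1/√16).
   It optimizes eight traits (*P_h*, *P_p*, *G_f*, *A_Max*, *S_G*, *R_u*,
   *W_sa*, *W_ss*) within germplasm-derived ranges, discarding candidates
   whose yield CV exceeds 10% or whose mean harvest index exceeds 0.64, with
   multi-start (one parent at the reference cultivar cv. Claire, the rest
   random).

## Worked example

Simulate 30 seasons of the reference winter wheat cv. Claire at Rothamsted
under the baseline climate (sown 20 October, rainfed, CO₂ 364 ppm):

```sh
$ wheatideo simulate --site RR --seasons 30 --seed 1
{
  "site": "RR",
  "scenario": "baseline",
  "water": "rainfed",
  "seed": 1,
  "mean_yield_t_ha": 10.19,
  "cv_pct": 6.65,
  "mean_hi": 0.444,
  "yield_percentiles": {"5": 9.12, "25": 9.82, "50": 10.24, "75": 10.75, "95": 10.91},
  "config_hash": "aebae689d4db"
}
```

Mean yield 10.2 t ha⁻¹ with a 6.7% inter-annual CV and harvest index 0.44 —
a good-year UK wheat crop under near-optimal management. Now design an
ideotype for the irrigated 2050 climate at the same site (two optimizer
starts, 30-season ensembles):

```sh
$ wheatideo optimize --site RR --water irrigated --seasons 30 --starts 2 --max-steps 100 --seed 1
{
  "site": "RR",
  "water": "irrigated",
  "seed": 1,
  "traits": {
    "p_h": 120.0,
    "p_p": 0.9,
    "tt_bgfegf": 891.95,
    "a_max": 0.01,
    "s_g": 0.705,
    "r_u": 2.69,
    "w_sa": 0.383,
    "w_ss": 1.7,
  },
  "mean_yield_t_ha": 19.34,
  "cv_pct": 3.35,
  "mean_hi": 0.453,
  "n_evaluations": 1042
}
```

The optimizer pushes the phyllochron to its 120 °C day upper bound (slower
leaf appearance keeps development in check under a warmer climate), extends
grain filling toward 900 °C day and maximizes flag-leaf area — together
nearly doubling yield relative to the current cultivar, while staying inside
the stability (CV ≤ 10%) and harvest-index (≤ 0.64) constraints. Under
irrigation the drought-tolerance traits (*W_sa*, *W_ss*) drift: they have no
effect on the objective, so their final values are a random walk.

The same pipeline is available as a library (`generate_series`,
`apply_scenario`, `simulate_ensemble`, `run_easa`, `run_experiment`), and
`wheatideo experiment` runs the full four-treatment design (current cultivar
under baseline and 2050 climate; rainfed and irrigated ideotypes under 2050)
across all six sites, writing per-season CSVs, report tables and a
provenance-stamped JSON summary.

## Layout

| module | contents |
| --- | --- |
| `wheatideo.weather` | generator, scenario morphing, site parameterizations, CSV I/O |
| `wheatideo.phenology` | thermal time, day length, vernalization, final leaf number |
| `wheatideo.canopy` | leaf layers, stay-green senescence, Beer-law interception |
| `wheatideo.soil` | layered water balance, root extraction, stress factors |
| `wheatideo.carbon` | RUE biomass, grain set under heat/drought, grain filling |
| `wheatideo.season` | daily orchestration, season/ensemble results |
| `wheatideo.easa` | the self-adaptive evolution strategy and feasibility filter |
| `wheatideo.experiments` / `wheatideo.cli` | treatment design, reports, CLI verbs |

Model assumptions, parameter defaults and known limitations are documented
in [docs/methods.md](docs/methods.md).
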