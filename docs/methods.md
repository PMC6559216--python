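# Methods

This note documents the model equations, the defaults and why they were
chosen, what the synthetic weather does and does not emulate, and the known
limitations. Symbols follow field convention (thermal times in °C day,
masses in g m⁻², water in mm, radiation in MJ m⁻² day⁻¹).

## Weather generation

Each site is described by twelve monthly parameter sets. Daily series are
generated on a 365-day calendar (no leap days), continuous across year
boundaries so that seasons spanning two calendar years (sowing 20 October →
maturity in August; 20 April → January–February) are supported.

* **Precipitation occurrence** is a first-order two-state Markov chain with
  monthly wet-after-wet and wet-after-dry probabilities (defaults 0.65 and
  0.35, stationary wet fraction 0.5). **Amounts** on wet days are gamma
  distributed (shape 0.8; the scale is solved per site so the expected
  annual total matches the site normal).
* **Temperature**: Tmin and Tmax are the monthly means plus one shared
  Gaussian deviation (SD 2 °C). Sharing the deviation preserves
  Tmax ≥ Tmin on every day and reproduces day-to-day variability without an
  autocorrelation model.
* **Radiation** is Gaussian (SD 20% of the monthly mean) around a dry-day or
  wet-day mean (dry = 1.1 × monthly mean; wet solved so the wet/dry mixture
  returns the monthly mean), truncated at zero.

Monthly means follow sinusoidal seasonality: temperature amplitude 5.5 °C
(UK) / 4.5 °C (NZ), radiation relative amplitude 0.85 / 0.75, warm peak in
July (UK) or January (NZ), a fixed 8 °C diurnal range, and aseasonal
precipitation. Only *annual* normals are constrained by the six sites'
observed 1980–2010 statistics; the monthly shapes are a modelling choice and
with 100 generated years reproduce the annual normals within ±0.3 °C, ±5%
precipitation and ±5% radiation (verified in the test suite).

Climate scenarios morph the monthly statistics: additive temperature
offsets, multiplicative factors on the precipitation gamma scale and on both
radiation means, and a CO₂ replacement. The built-in 2050 scenario applies
the country-level deltas uniformly across months (+2.1 °C and ×1.067
radiation in the UK; +1.9 °C and ×1.011 in NZ; CO₂ 541 ppm). The
precipitation change is stated only as a "small (<2%) decrease", fixed here
at ×0.98 for both countries.

What the generator does **not** emulate: temperature/radiation
autocorrelation beyond the wet/dry conditioning, precipitation seasonality,
extreme-event statistics (heat waves are only as frequent as independent
Gaussian draws allow), and any within-month trend. Tests passing against
this generator therefore say nothing about model behavior under realistic
heat-wave clustering.

## Crop model

One season runs daily from sowing to maturity (failsafe 400 days; a season
that never reaches anthesis is flagged and scored zero yield).

**Phenology.** Daily thermal time is max(0, (Tmin+Tmax)/2 − T_base) with
T_base = 0 °C. Emergence occurs at TT_SOWEM (150 °C day for cv. Claire).
After emergence the Haun stage advances by ΔTT / P_h. Vernalization
progresses at VBEE + VAI·T per day, capped at 1; on the day it saturates the
final leaf number is fixed as

FLN = clamp(L_Min + P_p · max(0, 20 h − DL), L_Min, L_Max),

where DL is that day's astronomical day length. The 20 h reference and the
1 leaf per (leaf h⁻¹) · h scaling are configurable; with them the reference
cultivar (P_p = 0.5) spans FLN ≈ 12–14 over UK/NZ winter day lengths, and
shorter days give more leaves. Before saturation development proceeds toward
the provisional maximum L_Max. Anthesis occurs 2.0 phyllochrons after the
Haun stage reaches FLN (the flag-leaf-to-anthesis lag is not observable from
the summary outputs; it is configurable). Begin/end of grain fill and
maturity follow at TT_ANBGF, G_f and TT_EGFMAT.

**Canopy.** Each mainstem leaf owns a layer whose potential area ramps
linearly from 0.25 × A_Max (leaf 1) to A_Max (flag leaf) and expands over
one phyllochron. Layer areas are per shoot; canopy LAI is the per-shoot
green area times a shoot density of 120 shoots m⁻², chosen so the reference
cultivar peaks near LAI ≈ 7.7–7.9 — without this scaling a 0.007 m² flag
leaf could never produce a closed canopy. After anthesis a uniform green
fraction declines linearly in *effective* senescence thermal time, delayed
by the fraction S_G/(1+S_G) of the anthesis-to-end-of-fill window; water
stress accelerates effective time by 1 + (W_ss − 1)(1 − FW), using the
previous day's FW (the canopy is updated before the soil water balance each
day). The canopy is forced to zero LAI at the end of grain fill regardless
of stay-green. Interception follows Beer's law with k = 0.45 on
PAR = 0.5 × global radiation.

**Soil water.** Thirty 5-cm layers hold equal shares of the profile's
available water capacity (210 mm "rothamsted_210", 270 mm "lincoln_270"),
full at sowing. Rain cascades top-down; excess drains. The root front grows
at 0.1 cm per °C day from 5 cm at sowing (reaching the 150 cm profile bottom
at 1450 °C day, around anthesis for winter sowings). The daily extractable
fraction declines linearly from 10% at the surface to R_u % at the root
front, evaluated at layer tops. Transpiration demand is a Priestley–Taylor
equilibrium evaporation (α = 1.26, net radiation 0.8 × global, λ = 2.45
MJ kg⁻¹) times the intercepted-light fraction; FW = min(1, supply/demand)
and the actual uptake min(supply, demand) is removed proportionally to each
layer's extractable amount. Daily water balance closes to 10⁻⁹ mm. Soil
evaporation is not modelled; the available-water-capacity semantics absorb
it. Irrigated ("potential") runs pin FW to 1 and skip the balance entirely
rather than schedule irrigation events.

**Biomass and grain.** Daily growth is intercepted PAR × RUE × modifiers.
RUE at the 338 ppm reference is 2.7 g MJ⁻¹ PAR; the CO₂ multiplier is
linear, +30% per doubling from 338 ppm (1.180 at 541 ppm). The temperature
factor is min(1, T/10 °C) — a deliberately minimal representation whose main
effect is slowing winter growth — and water stress multiplies growth by
1 − W_sa(1 − FW). Grain number is set at the beginning of grain fill from

GN = GNEar · 0.17 · B_anthesis · (1 − heat) · (1 − drought),

where the ear fraction 0.17 of anthesis biomass is calibrated so the
reference cultivar sets 22–28 × 10³ grains m⁻² (10–13 t ha⁻¹ at the 0.045 g
per-grain cap with HI ≈ 0.44–0.47) from its simulated anthesis biomass of
~1400 g m⁻². The heat reduction is min(1, HSGNR · Σ max(0, Tmax − HSGNT))
over the window anthesis ± TT_ANBGF; the drought reduction is piecewise
linear in DSF (zero at DSF ≥ 0.90, maximal 0.20 at DSF ≤ 0.30), with DSF the
mean FW from 300 °C day before anthesis to the beginning of grain fill.
During grain fill the grain receives new assimilate plus the labile pool
(25% of anthesis biomass) released uniformly per unit thermal time over G_f,
capped by grain number × 0.045 g; if the canopy dies early, the unreleased
pool is forfeited. Yields are reported in t ha⁻¹ (1 g m⁻² = 0.01 t ha⁻¹).

The daily loop lives in a single scalar function compiled with numba when
available (identical Python otherwise); a test replays whole seasons through
the public operation-level functions and requires agreement to 10⁻⁹.

## Optimization

The EASA optimizer is a (1+λ) evolution strategy, λ = 16 offspring per
step. Each candidate carries one step size per trait; offspring evolve the
steps log-normally (σ′ = σ·exp(τN), τ = 1/√(2·8), clamped to [10⁻³, 0.5] ×
range width) and then perturb values Gaussianly, clamped to the trait
ranges. Selection is elitist over feasible candidates (yield CV ≤ 10%, mean
HI ≤ 0.64 — both non-strict, matching removal only of candidates *over* the
limits); when a generation brings no improvement the retained parent's steps
shrink by 0.85, a success-rule element without which a stalled elitist
parent would keep oversized steps indefinitely (observed to plateau at ~3%
of range width; with the decay, separable concave test objectives are
recovered to ≤0.5%). A run stops after 20 steps without >10⁻³ t ha⁻¹
improvement or at 200 steps. Multi-start uses 8 parents by default, one
fixed at cv. Claire, the rest uniform in the ranges; every candidate within
a run is evaluated on the same weather realization, so the objective is
deterministic and selection noise-free. The HI constraint applies to the
ensemble-mean HI.

With the default ear fraction the grain sink is at most 0.54 × anthesis
biomass, which is below 0.64 × total biomass, so the HI ceiling cannot bind
under this model structure; it is enforced anyway and becomes active if the
ear fraction or grain-weight cap is reconfigured.

## Ensembles, experiments and problem sizes

Ensembles simulate one season per consecutive sowing year; statistics are
the mean, sample (n−1) SD, CV = 100·SD/mean, and 5/25/50/75/95 percentiles
by linear interpolation between order statistics. The full experiment runs
100-season ensembles and 8-start optimizations per site and water mode. The
test suite and the acceptance script use scaled-down problem sizes — 10–30
season ensembles, 1–2 optimizer starts, ≤100 steps — chosen as the smallest
sizes at which the ensemble statistics and optimizer convergence are stable;
they finish in seconds because of the compiled core.

## Known limitations

* Phenology is purely thermal-time driven between fixed stage thresholds;
  warming therefore advances anthesis more strongly (~1 month under the 2050
  scenario) than a leaf-appearance model with photoperiod modulation would
  (~11 days in calibrated references). Directional responses (warming never
  delays stages, season shortens) are correct.
* Nitrogen is assumed non-limiting; disease, pests, weeds, frost kill and
  tillering dynamics are out of scope.
* No direct heat reduction of potential grain weight during filling; heat
  acts on grain number, and early canopy death is the only filling
  truncation.
* The weather generator's simplifications (above) understate extreme-event
  clustering, so absolute stress frequencies are indicative only.
* Absolute yield levels depend on the RUE/ear-fraction/shoot-density
  calibration; cross-site and cross-treatment *contrasts* are the model's
  robust outputs.
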