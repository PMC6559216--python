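"""Evolutionary search algorithm with self-adaptation (EASA).

A (1+λ) evolution strategy over the eight optimizable cultivar traits.
Each candidate carries, alongside its trait values, one mutation step size
per trait; offspring inherit the parent's step sizes mutated log-normally
(τ = 1/√(2n)) and perturb each trait by a Gaussian of the evolved step, so
the search distribution adapts as the optimization proceeds.  Per step, λ
(default 16) offspring are generated; the next parent is the feasible
candidate with the highest mean yield among the offspring and the incumbent
parent (elitist), where feasibility demands a yield CV of at most 10% (high
yield stability) and a mean harvest index of at most 0.64 (the reported
upper limit).  Multi-start: one parent starts from cv. Claire, the others
uniformly at random in the trait ranges; the best feasible candidate over
all starts is the optimal ideotype.

The evaluator maps a trait vector to (mean yield, yield CV %, mean HI);
within one optimization every candidate is evaluated on the same fixed
weather realization (common random numbers), so the objective is
deterministic and selection noise-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .cultivar import CLAIRE, CultivarParams, TRAIT_NAMES, TRAIT_RANGES
from .season import SimConfig, simulate_ensemble
from .weather import WeatherSeries

__all__ = [
    "OptimizationSpec", "EvalRecord", "Candidate", "OptimizationResult",
    "mutate", "evaluate", "easa_step", "run_easa", "make_yield_evaluator",
]

Evaluator = Callable[[np.ndarray], tuple[float, float, float]]


@dataclass(frozen=True)
class OptimizationSpec:
    """Search space, feasibility ceilings and stopping rules."""

    ranges: dict = field(default_factory=lambda: dict(TRAIT_RANGES))
    offspring: int = 16
    starts: int = 8
    cv_max_pct: float = 10.0       # yield-stability ceiling
    hi_max: float = 0.64           # harvest-index ceiling
    patience: int = 20             # steps without improvement before stopping
    max_steps: int = 200
    improvement_tol: float = 1e-3  # t ha-1
    init_step_frac: float = 0.1    # initial step size as fraction of range width
    step_min_frac: float = 1e-3    # step-size clamp, fraction of range width
    step_max_frac: float = 0.5
    stall_decay: float = 0.85      # step shrink when a generation fails to improve
    base: CultivarParams = CLAIRE

    def __post_init__(self) -> None:
        if self.offspring < 1:
            raise ValueError("offspring must be >= 1")
        if self.starts < 1:
            raise ValueError("starts must be >= 1")
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {name} is not well-ordered: [{lo}, {hi}]")
        if self.cv_max_pct <= 0 or self.hi_max <= 0:
            raise ValueError("feasibility ceilings must be positive")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.ranges)

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.ranges.values()])

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.ranges.values()])

    @property
    def width(self) -> np.ndarray:
        return self.hi - self.lo

    @property
    def tau(self) -> float:
        return 1.0 / np.sqrt(2.0 * len(self.ranges))


@dataclass(frozen=True)
class EvalRecord:
    mean_yield: float
    cv_pct: float
    mean_hi: float
    feasible: bool
    error: str = ""


@dataclass(frozen=True)
class Candidate:
    """Trait vector plus self-adaptive mutation step sizes."""

    values: np.ndarray
    steps: np.ndarray
    record: EvalRecord | None = None

    @property
    def evaluated(self) -> bool:
        return self.record is not None


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of a multi-start EASA run."""

    best: Candidate | None             # overall best feasible candidate
    start_bests: tuple                 # best feasible per start (None if none)
    trajectory: tuple                  # (start, step, parent mean yield) rows
    feasible_log: tuple                # EvalRecords of every feasible candidate
    n_evaluations: int

    @property
    def succeeded(self) -> bool:
        return self.best is not None

    def best_cultivar(self, spec: OptimizationSpec) -> CultivarParams:
        if self.best is None:
            raise ValueError("optimization found no feasible candidate")
        return spec.base.with_traits(dict(zip(spec.names, self.best.values)))


def mutate(parent: Candidate, spec: OptimizationSpec,
           rng: np.random.Generator) -> Candidate:
    """One self-adaptive mutation: evolve step sizes, then perturb values.

    Per coordinate, ``step' = step × exp(τ N(0,1))`` clamped to the
    per-range bounds and ``value' = value + step' N(0,1)`` clamped to the
    trait range; the offspring inherits the evolved steps.
    """
    steps = parent.steps * np.exp(spec.tau * rng.standard_normal(len(parent.steps)))
    steps = np.clip(steps, spec.step_min_frac * spec.width,
                    spec.step_max_frac * spec.width)
    values = np.clip(parent.values + steps * rng.standard_normal(len(steps)),
                     spec.lo, spec.hi)
    return Candidate(values=values, steps=steps)


def evaluate(candidate: Candidate, evaluator: Evaluator,
             spec: OptimizationSpec) -> Candidate:
    """Attach an evaluation record; feasible ⇔ CV ≤ ceiling and HI ≤ ceiling.

    An evaluator failure marks the candidate infeasible instead of raising.
    """
    try:
        mean_yield, cv_pct, mean_hi = evaluator(candidate.values)
    except Exception as exc:  # noqa: BLE001 - optimizer robustness
        rec = EvalRecord(float("-inf"), float("inf"), float("inf"),
                         feasible=False, error=str(exc))
        return replace(candidate, record=rec)
    feasible = (cv_pct <= spec.cv_max_pct) and (mean_hi <= spec.hi_max)
    return replace(candidate, record=EvalRecord(
        float(mean_yield), float(cv_pct), float(mean_hi), feasible))


def easa_step(parent: Candidate, spec: OptimizationSpec, evaluator: Evaluator,
              rng: np.random.Generator) -> tuple[Candidate, list[Candidate]]:
    """One elitist generation: λ offspring, select best feasible incl. parent.

    Returns (next parent, evaluated offspring).  If no offspring is feasible
    and the parent is infeasible, the parent is retained as the search
    position.
    """
    if not parent.evaluated:
        raise ValueError("parent must be evaluated before stepping")
    offspring = [evaluate(mutate(parent, spec, rng), evaluator, spec)
                 for _ in range(spec.offspring)]
    pool = [c for c in offspring + [parent] if c.record.feasible]
    if not pool:
        return parent, offspring
    best = max(pool, key=lambda c: c.record.mean_yield)
    # elitism: never move to a feasible candidate worse than a feasible parent
    if parent.record.feasible and best.record.mean_yield <= parent.record.mean_yield:
        # a stalled elitist parent would otherwise keep its step sizes forever;
        # shrink them (success-rule style) so the search can refine locally
        decayed = np.maximum(parent.steps * spec.stall_decay,
                             spec.step_min_frac * spec.width)
        return replace(parent, steps=decayed), offspring
    return best, offspring


def run_easa(spec: OptimizationSpec, evaluator: Evaluator,
             seed: "int | np.random.SeedSequence",
             claire_start: bool = True) -> OptimizationResult:
    """Multi-start EASA; returns the overall best feasible candidate.

    The first start is the base cultivar (cv. Claire) when ``claire_start``;
    the remaining ``starts − 1`` parents are uniform in the trait ranges.
    A start stops when its best mean yield has not improved by more than
    ``improvement_tol`` for ``patience`` consecutive steps, or at
    ``max_steps``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    start_seeds = ss.spawn(spec.starts)
    trajectory: list[tuple[int, int, float]] = []
    feasible_log: list[EvalRecord] = []
    start_bests: list[Candidate | None] = []
    n_eval = 0

    for s_idx, s_seed in enumerate(start_seeds):
        rng = np.random.default_rng(s_seed)
        if s_idx == 0 and claire_start:
            values = np.clip(spec.base.trait_vector() if spec.names == TRAIT_NAMES
                             else np.array([getattr(spec.base, n) for n in spec.names]),
                             spec.lo, spec.hi)
        else:
            values = rng.uniform(spec.lo, spec.hi)
        parent = evaluate(Candidate(values=values, steps=spec.init_step_frac * spec.width),
                          evaluator, spec)
        n_eval += 1
        best: Candidate | None = parent if parent.record.feasible else None
        if parent.record.feasible:
            feasible_log.append(parent.record)
        best_yield = best.record.mean_yield if best else float("-inf")
        stall = 0
        for step in range(spec.max_steps):
            parent, offspring = easa_step(parent, spec, evaluator, rng)
            n_eval += spec.offspring
            for c in offspring:
                if c.record.feasible:
                    feasible_log.append(c.record)
                    if best is None or c.record.mean_yield > best.record.mean_yield:
                        best = c
            trajectory.append((s_idx, step, parent.record.mean_yield))
            new_best = best.record.mean_yield if best else float("-inf")
            if new_best > best_yield + spec.improvement_tol:
                best_yield = new_best
                stall = 0
            else:
                stall += 1
                if stall >= spec.patience:
                    break
        start_bests.append(best)

    feasible_bests = [b for b in start_bests if b is not None]
    overall = max(feasible_bests, key=lambda c: c.record.mean_yield) \
        if feasible_bests else None
    return OptimizationResult(
        best=overall, start_bests=tuple(start_bests),
        trajectory=tuple(trajectory), feasible_log=tuple(feasible_log),
        n_evaluations=n_eval)


def make_yield_evaluator(weather: WeatherSeries, config: SimConfig,
                         base: CultivarParams = CLAIRE,
                         n_seasons: int | None = None,
                         names: Sequence[str] = TRAIT_NAMES) -> Evaluator:
    """Evaluator closure: trait vector → (mean yield, CV %, mean HI).

    All candidates share the one weather realization passed in, so the
    objective is deterministic (common random numbers).
    """
    def _eval(values: np.ndarray) -> tuple[float, float, float]:
        cultivar = base.with_traits(dict(zip(names, values)))
        ens = simulate_ensemble(cultivar, weather, config, n_seasons=n_seasons)
        return ens.mean_yield, ens.cv_pct, ens.mean_hi
    return _eval
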