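"""Self-adaptive evolution strategy: mutation, feasibility, selection, recovery."""

import numpy as np
import pytest

import wheatideo.easa as ea
from wheatideo.cultivar import CLAIRE, TRAIT_NAMES, TRAIT_RANGES


def make_spec(**kw):
    return ea.OptimizationSpec(**kw)


def mid_candidate(spec, step_frac=0.1):
    values = 0.5 * (spec.lo + spec.hi)
    return ea.Candidate(values=values, steps=step_frac * spec.width)


class _ZeroNormalRng:
    """Stub RNG whose standard normals are all zero."""

    def standard_normal(self, n):
        return np.zeros(n)


class TestMutate:
    def test_zero_draws_leave_values_unchanged(self):
        spec = make_spec()
        parent = mid_candidate(spec)
        child = ea.mutate(parent, spec, _ZeroNormalRng())
        np.testing.assert_allclose(child.values, parent.values)

    def test_offspring_always_within_ranges(self):
        spec = make_spec()
        rng = np.random.default_rng(0)
        parent = ea.Candidate(values=spec.lo.copy(), steps=0.5 * spec.width)
        for _ in range(2000):
            child = ea.mutate(parent, spec, rng)
            assert np.all(child.values >= spec.lo - 1e-12)
            assert np.all(child.values <= spec.hi + 1e-12)
            assert np.all(child.steps >= spec.step_min_frac * spec.width - 1e-15)
            assert np.all(child.steps <= spec.step_max_frac * spec.width + 1e-15)
            parent = child

    def test_empirical_spread_matches_monte_carlo_oracle(self):
        # far from the bounds, the per-coordinate offspring SD equals the SD of
        # step * exp(tau N) * N, estimated by an independent Monte Carlo oracle
        spec = make_spec()
        parent = mid_candidate(spec, step_frac=0.05)
        rng = np.random.default_rng(1)
        deltas = np.array([ea.mutate(parent, spec, rng).values - parent.values
                           for _ in range(10_000)])
        oracle_rng = np.random.default_rng(2)
        z1 = oracle_rng.standard_normal(10**6)
        z2 = oracle_rng.standard_normal(10**6)
        factor = np.std(np.exp(spec.tau * z1) * z2)
        for i in range(len(TRAIT_NAMES)):
            expected = 0.05 * spec.width[i] * factor
            assert deltas[:, i].std() == pytest.approx(expected, rel=0.10)


class TestEvaluate:
    @pytest.mark.parametrize("cv,hi,feasible", [
        (12.0, 0.5, False),   # CV above the 10% stability ceiling
        (10.0, 0.5, True),    # exactly at the ceiling is acceptable
        (5.0, 0.64, True),    # HI exactly at the reported upper limit
        (5.0, 0.641, False),  # strictly over the HI limit
        (0.0, 0.5, True),
    ])
    def test_feasibility_rule(self, cv, hi, feasible):
        spec = make_spec()
        cand = ea.evaluate(mid_candidate(spec),
                           lambda v: (10.0, cv, hi), spec)
        assert cand.record.feasible is feasible

    def test_evaluator_failure_marks_infeasible(self):
        spec = make_spec()

        def broken(v):
            raise RuntimeError("boom")

        cand = ea.evaluate(mid_candidate(spec), broken, spec)
        assert not cand.record.feasible
        assert "boom" in cand.record.error


class TestStep:
    def test_constant_objective_retains_parent(self):
        spec = make_spec(offspring=16)
        rng = np.random.default_rng(3)
        parent = ea.evaluate(mid_candidate(spec), lambda v: (5.0, 1.0, 0.5), spec)
        nxt, offspring = ea.easa_step(parent, spec, lambda v: (5.0, 1.0, 0.5),
                                      rng)
        assert len(offspring) == 16
        assert nxt.record.mean_yield == parent.record.mean_yield

    def test_all_offspring_infeasible_retains_parent(self):
        spec = make_spec()
        rng = np.random.default_rng(4)
        parent = ea.evaluate(mid_candidate(spec), lambda v: (5.0, 1.0, 0.5), spec)
        nxt, _ = ea.easa_step(parent, spec, lambda v: (9.0, 99.0, 0.5), rng)
        np.testing.assert_array_equal(nxt.values, parent.values)
        assert nxt.record == parent.record
        # the retained parent's steps shrink so the search can refine
        assert np.all(nxt.steps <= parent.steps)


def quadratic_objective(center):
    def f(values):
        return -float(np.sum(((values - center)) ** 2)), 1.0, 0.5
    return f


class TestRun:
    def test_monotone_objective_reaches_phyllochron_upper_bound(self):
        spec = make_spec(starts=2, max_steps=120, patience=30)
        result = ea.run_easa(spec, lambda v: (float(v[0]), 1.0, 0.5), seed=5)
        assert result.succeeded
        p_h = result.best.values[0]
        assert p_h >= 120.0 - 0.01 * (120.0 - 70.0)  # within 1% of the bound

    def test_recovers_known_optimum_within_one_percent_of_width(self):
        spec = make_spec(starts=2, max_steps=200)
        center = spec.lo + 0.5 * spec.width
        scaled = lambda v: (-float(np.sum(((v - center) / spec.width) ** 2)),
                            1.0, 0.5)
        result = ea.run_easa(spec, scaled, seed=6)
        err = np.abs(result.best.values - center) / spec.width
        assert np.all(err <= 0.01)

    def test_single_start_from_claire_finds_same_optimum(self):
        center = make_spec().lo + 0.5 * make_spec().width
        multi = ea.run_easa(make_spec(starts=4, max_steps=150),
                            quadratic_objective(center), seed=7)
        single = ea.run_easa(make_spec(starts=1, max_steps=150),
                             quadratic_objective(center), seed=7)
        gap = np.abs(multi.best.values - single.best.values) / make_spec().width
        assert np.all(gap <= 0.02)

    def test_trajectory_best_is_monotone_under_elitism(self):
        spec = make_spec(starts=1, max_steps=60)
        center = spec.lo + 0.3 * spec.width
        result = ea.run_easa(spec, quadratic_objective(center), seed=8)
        yields = [y for (_s, _t, y) in result.trajectory]
        assert all(b >= a - 1e-12 for a, b in zip(yields, yields[1:]))

    def test_all_feasible_candidates_satisfy_ceilings(self):
        spec = make_spec(starts=1, max_steps=30)

        def noisy(v):
            cv = float(20.0 * (v[0] - spec.lo[0]) / spec.width[0])
            return float(v[0]), cv, 0.5

        result = ea.run_easa(spec, noisy, seed=9)
        assert len(result.feasible_log) > 0
        for rec in result.feasible_log:
            assert rec.cv_pct <= spec.cv_max_pct
            assert rec.mean_hi <= spec.hi_max

    def test_no_feasible_candidate_gives_explicit_failure(self):
        spec = make_spec(starts=1, max_steps=5, patience=3)
        result = ea.run_easa(spec, lambda v: (1.0, 99.0, 0.9), seed=10)
        assert not result.succeeded
        assert result.best is None
        with pytest.raises(ValueError, match="no feasible"):
            result.best_cultivar(spec)

    def test_deterministic_given_seed(self):
        spec = make_spec(starts=2, max_steps=25)
        center = spec.lo + 0.7 * spec.width
        a = ea.run_easa(spec, quadratic_objective(center), seed=11)
        b = ea.run_easa(spec, quadratic_objective(center), seed=11)
        np.testing.assert_array_equal(a.best.values, b.best.values)
        assert a.trajectory == b.trajectory

    def test_claire_start_is_claire(self):
        spec = make_spec(starts=1, max_steps=1, patience=1)
        seen = []
        result = ea.run_easa(spec, lambda v: (seen.append(v.copy()) or 1.0,
                                              1.0, 0.5), seed=12)
        np.testing.assert_allclose(seen[0], CLAIRE.trait_vector())


def test_trait_ranges_are_the_optimization_table():
    assert TRAIT_RANGES["p_h"] == (70.0, 120.0)
    assert TRAIT_RANGES["p_p"] == (0.065, 0.900)
    assert TRAIT_RANGES["tt_bgfegf"] == (500.0, 900.0)
    assert TRAIT_RANGES["a_max"] == (0.005, 0.010)
    assert TRAIT_RANGES["s_g"] == (0.0, 1.5)
    assert TRAIT_RANGES["r_u"] == (1.0, 5.0)
    assert TRAIT_RANGES["w_sa"] == (0.1, 1.0)
    assert TRAIT_RANGES["w_ss"] == (1.0, 1.7)
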