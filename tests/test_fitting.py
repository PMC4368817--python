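"""Objective function and genetic-algorithm behaviour."""

import numpy as np
import pytest
from dataclasses import replace

from epperm.fitting import FitContext, GAConfig, fit_group, ga_optimize, objective
from epperm.pk import PKParams
from epperm.synthetic import default_truth, simulate_trace
from epperm.trace import normalize_trace, subtract_background

from conftest import FAST_GA, TRUE_D_SAT, TRUE_DELAY, TRUE_RAMP

TINY_GA = dict(population=8, max_generations=3, polish=False)


def fresh_context(ctx):
    return replace(ctx, grid=ctx.grid, _cache={}, failures=[])


class TestObjective:
    def test_zero_at_generator_truth(self, norm_trace, true_context):
        obj = objective((TRUE_D_SAT, TRUE_DELAY, TRUE_RAMP), norm_trace, fresh_context(true_context))
        assert obj < 1e-6

    def test_impermeable_candidate_misses_the_rise(self, norm_trace, true_context):
        ctx = fresh_context(true_context)
        at_truth = objective((TRUE_D_SAT, TRUE_DELAY, TRUE_RAMP), norm_trace, ctx)
        no_leak = objective((0.0001, TRUE_DELAY, TRUE_RAMP), norm_trace, ctx)
        assert no_leak > at_truth

    def test_invariant_to_raw_trace_rescaling(self, noiseless_ds, true_context):
        theta = (TRUE_D_SAT, TRUE_DELAY, TRUE_RAMP)
        tr = noiseless_ds.trace
        scaled = replace(tr, values=5.0 * tr.values)
        a = objective(theta, normalize_trace(subtract_background(tr)), fresh_context(true_context))
        b = objective(theta, normalize_trace(subtract_background(scaled)), fresh_context(true_context))
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_cache_hit_returns_identical_value(self, norm_trace, true_context):
        ctx = fresh_context(true_context)
        theta = (0.005, 30.0, 200.0)
        assert objective(theta, norm_trace, ctx) == objective(theta, norm_trace, ctx)
        assert len(ctx._cache) == 1


class TestGA:
    def test_config_validation(self):
        with pytest.raises(ValueError, match="population"):
            GAConfig(population=3)
        with pytest.raises(ValueError, match="bounds"):
            GAConfig(d_sat_bounds=(0.1, 0.1))

    def test_seeded_determinism(self, norm_trace, true_context):
        cfg = GAConfig(seed=42, **TINY_GA)
        a = ga_optimize(norm_trace, fresh_context(true_context), cfg)
        b = ga_optimize(norm_trace, fresh_context(true_context), cfg)
        assert a.wall == b.wall
        assert a.objective == b.objective
        np.testing.assert_array_equal(a.history, b.history)

    def test_best_objective_never_increases(self, norm_trace, true_context):
        cfg = GAConfig(seed=0, population=10, max_generations=6, polish=False)
        res = ga_optimize(norm_trace, fresh_context(true_context), cfg)
        assert np.all(np.diff(res.history) <= 1e-16)

    def test_estimates_respect_bounds(self, norm_trace, true_context):
        cfg = GAConfig(seed=5, **TINY_GA)
        res = ga_optimize(norm_trace, fresh_context(true_context), cfg)
        assert cfg.d_sat_bounds[0] <= res.d_sat <= cfg.d_sat_bounds[1]
        assert cfg.delay_bounds[0] <= res.delay <= cfg.delay_bounds[1]
        assert cfg.ramp_bounds[0] <= res.ramp <= cfg.ramp_bounds[1]

    def test_fitted_dsat_increases_with_true_dsat(self, schedule):
        # identifiability: doubling the true wall coefficient moves the fit up
        fitted = []
        for i, d_sat in enumerate((0.002, 0.008, 0.032)):
            ds = simulate_trace(schedule, default_truth(schedule, d_sat=d_sat, noise_cv=0.0))
            tr = normalize_trace(subtract_background(ds.trace))
            ctx = FitContext(pk=PKParams(), t_fd=schedule.t_fd, t_ep=schedule.t_ep, d_tiss=30.0)
            res = ga_optimize(tr, ctx, GAConfig(seed=20 + i, population=10, max_generations=6, polish_maxiter=120))
            fitted.append(res.d_sat)
        assert fitted[0] < fitted[1] < fitted[2]


class TestGroup:
    def test_single_trace_median_is_its_value(self, norm_trace, true_context):
        cfg = GAConfig(seed=1, **TINY_GA)
        group = fit_group([norm_trace], fresh_context(true_context), cfg)
        assert group.median_d_sat == group.results[0].d_sat
        assert group.failures == []

    def test_empty_group_rejected(self, true_context):
        with pytest.raises(ValueError, match="at least one"):
            fit_group([], true_context)


def test_full_pipeline_recovery_noiseless(noiseless_results):
    """Analysis surface: generate -> normalize -> PK fit -> GA recovers the truth."""
    res = noiseless_results
    assert res.d_wall == pytest.approx(TRUE_D_SAT, rel=0.10)
    assert res.delay == pytest.approx(TRUE_DELAY, rel=0.10)
    assert res.ramp == pytest.approx(TRUE_RAMP, rel=0.10)
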