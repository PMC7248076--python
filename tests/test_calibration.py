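"""Log-deviation fitness, (1+3)-evolution strategy and synthetic targets."""

import dataclasses
import math

import numpy as np
import pytest

from ferropoiesis import presets
from ferropoiesis.calibration import (CalibrationError, FitSpec,
                                      TimeSeriesDataset, es_optimize, fitness,
                                      make_objective, synthesize_dataset)

GRID = np.arange(0.0, 3.0 + 1e-9, 1e-3)


class TestFitnessMetric:
    def test_identical_curves_score_zero(self):
        ds = TimeSeriesDataset("x", GRID, np.full(GRID.size, 2.5))
        assert fitness((GRID, np.full(GRID.size, 2.5)), ds) == 0.0

    def test_constant_factor_e_over_unit_interval_scores_one(self):
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-3)
        ds = TimeSeriesDataset("x", grid, np.ones(grid.size))
        val = fitness((grid, math.e * np.ones(grid.size)), ds)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_factor_two_over_three_days_scores_3log2(self):
        ds = TimeSeriesDataset("x", GRID, np.ones(GRID.size))
        val = fitness((GRID, 2.0 * np.ones(GRID.size)), ds)
        assert val == pytest.approx(3.0 * math.log(2.0), abs=1e-6)

    def test_scale_invariance(self, rng):
        t = np.linspace(0.0, 10.0, 101)
        a = 1.0 + rng.random(t.size)
        b = 1.0 + rng.random(t.size)
        ds_b = TimeSeriesDataset("x", t, b)
        ds_cb = TimeSeriesDataset("x", t, 7.3 * b)
        assert fitness((t, a), ds_b) == pytest.approx(
            fitness((t, 7.3 * a), ds_cb), rel=1e-12)

    def test_multiple_datasets_add(self):
        ds = TimeSeriesDataset("x", GRID, np.ones(GRID.size))
        single = fitness((GRID, 2.0 * np.ones(GRID.size)), ds)
        double = fitness((GRID, 2.0 * np.ones(GRID.size)), [ds, ds])
        assert double == pytest.approx(2.0 * single)

    def test_nonpositive_model_value_is_reported(self):
        ds = TimeSeriesDataset("x", np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(CalibrationError, match="'x'"):
            fitness((np.array([0.0, 1.0]), np.array([1.0, -0.5])), ds)

    def test_dataset_validation(self):
        with pytest.raises(CalibrationError, match="strictly increasing"):
            TimeSeriesDataset("x", np.array([0.0, 0.0, 1.0]), np.ones(3))
        with pytest.raises(CalibrationError, match="nonpositive"):
            TimeSeriesDataset("x", np.array([0.0, 1.0]), np.array([1.0, 0.0]))


def _sphere(target):
    def objective(values):
        return sum((math.log(v) - math.log(target[k])) ** 2
                   for k, v in values.items())
    return objective


class TestEvolutionStrategy:
    BOUNDS = {"a": (0.1, 10.0), "b": (0.1, 10.0)}

    def test_zero_mutation_step_freezes_the_parent(self):
        spec = FitSpec(parameters=self.BOUNDS, initial_step=0.0,
                       generations=25, seed=0)
        res = es_optimize(spec, _sphere({"a": 2.0, "b": 0.5}))
        assert np.all(res.trace == res.trace[0])

    def test_trace_is_non_increasing_elitist(self):
        spec = FitSpec(parameters=self.BOUNDS, generations=60, seed=1)
        res = es_optimize(spec, _sphere({"a": 3.0, "b": 0.3}))
        assert np.all(np.diff(res.trace) <= 0)

    def test_two_parameter_recovery_on_smooth_objective(self):
        spec = FitSpec(parameters=self.BOUNDS, generations=150, seed=2,
                       initial_step=0.3)
        res = es_optimize(spec, _sphere({"a": 2.0, "b": 0.5}))
        assert res.best["a"] == pytest.approx(2.0, rel=0.05)
        assert res.best["b"] == pytest.approx(0.5, rel=0.05)

    def test_reproducible_under_fixed_seed(self):
        spec = FitSpec(parameters=self.BOUNDS, generations=30, seed=11)
        r1 = es_optimize(spec, _sphere({"a": 1.0, "b": 1.0}))
        r2 = es_optimize(spec, _sphere({"a": 1.0, "b": 1.0}))
        assert r1.best == r2.best
        np.testing.assert_array_equal(r1.trace, r2.trace)

    def test_unviable_children_do_not_kill_the_run(self):
        calls = {"n": 0}

        def flaky(values):
            calls["n"] += 1
            if values["a"] > 2.0:
                raise CalibrationError("unviable")
            return (math.log(values["a"]) - math.log(1.5)) ** 2

        spec = FitSpec(parameters={"a": (0.5, 8.0)}, start={"a": 1.0},
                       generations=80, seed=3)
        res = es_optimize(spec, flaky)
        assert res.best["a"] == pytest.approx(1.5, rel=0.1)

    def test_persistent_failure_raises_after_retries(self):
        def broken(values):
            if values["a"] != 1.0:
                raise CalibrationError("always fails")
            return 1.0

        spec = FitSpec(parameters={"a": (0.999, 1.001)}, start={"a": 1.0},
                       generations=100, seed=4, initial_step=5.0,
                       max_failed_generations=5)
        # children are clipped to the bounds so they differ from the parent
        # and always fail; the run must abort with a diagnostic
        with pytest.raises(CalibrationError, match="consecutive"):
            es_optimize(spec, broken)

    def test_invalid_specs_rejected(self):
        with pytest.raises(CalibrationError):
            FitSpec(parameters={})
        with pytest.raises(CalibrationError):
            FitSpec(parameters={"a": (1.0, 0.5)})
        with pytest.raises(CalibrationError):
            FitSpec(parameters={"a": (-1.0, 2.0)})
        with pytest.raises(CalibrationError):
            FitSpec(parameters={"a": (0.5, 2.0)}, start={"a": 3.0})


class TestSynthesizeDataset:
    def test_noiseless_samples_match_trajectory(self, params, scenario_lib):
        from ferropoiesis import simulate

        sc = dataclasses.replace(scenario_lib["iv_iron_100mg"], horizon=10.0)
        times = np.arange(0.0, 10.1, 1.0)
        (ds,) = synthesize_dataset(params, sc, ["ferritin"], times,
                                   noise_cv=0.0, seed=0, grid=0.25, rtol=1e-6)
        traj = simulate(sc, params, grid=0.25, rtol=1e-6)
        expected = np.interp(times, traj.times, traj.series("ferritin"))
        np.testing.assert_allclose(ds.values, expected, rtol=1e-12)
        assert ds.sd is None

    def test_fixed_seed_reproducible(self, params, scenario_lib):
        sc = dataclasses.replace(scenario_lib["iv_iron_100mg"], horizon=5.0)
        times = np.arange(0.0, 5.1, 1.0)
        a = synthesize_dataset(params, sc, ["HB"], times, 0.1, seed=5,
                               grid=0.5, rtol=1e-6)
        b = synthesize_dataset(params, sc, ["HB"], times, 0.1, seed=5,
                               grid=0.5, rtol=1e-6)
        np.testing.assert_array_equal(a[0].values, b[0].values)

    def test_noise_cv_calibrated_by_monte_carlo(self, params):
        # replicate draws of one sampled point have sample CV ~ noise_cv
        from ferropoiesis import Scenario

        sc = Scenario(label="flat", horizon=1.0)
        times = np.array([0.0, 1.0])
        base = synthesize_dataset(params, sc, ["HB"], times, 0.0, seed=0,
                                  grid=0.5, rtol=1e-6)[0].values[1]
        draws = np.array([
            synthesize_dataset(params, sc, ["HB"], times, 0.1, seed=s,
                               grid=0.5, rtol=1e-6)[0].values[1]
            for s in range(1000)])
        assert np.std(draws) / np.mean(draws) == pytest.approx(0.1, abs=0.01)
        sd = synthesize_dataset(params, sc, ["HB"], times, 0.1, seed=1,
                                grid=0.5, rtol=1e-6)[0].sd
        np.testing.assert_allclose(sd, 0.1 * base, rtol=1e-9)

    def test_negative_cv_rejected(self, params, scenario_lib):
        with pytest.raises(CalibrationError):
            synthesize_dataset(params, scenario_lib["iv_iron_100mg"], ["HB"],
                               [0.0, 1.0], -0.1, seed=0)
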