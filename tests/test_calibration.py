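"""Objective construction, pattern search, and parameter recovery."""

import numpy as np
import pytest

from conftest import build_mini_model, mini_datasets
from hgfmet.calibrate import (
    CalibrationModel,
    ExperimentDataset,
    PENALTY_COST,
    fit_inhibitor_strengths,
    objective,
    pattern_search,
)
from hgfmet.simulate import Condition


class TestObjective:
    def test_self_consistency_is_zero(self, mini_model):
        data = mini_datasets(mini_model)
        cost = objective(mini_model, data)
        assert cost == pytest.approx(0.0, abs=1e-6)

    def test_perturbed_parameter_increases_cost(self, mini_model):
        data = mini_datasets(mini_model)
        base = objective(mini_model, data)
        worse = objective(mini_model, data, params={"k_act_B": 1e-3})
        assert worse > base + 1e-3

    def test_empty_datasets_rejected(self, mini_model):
        with pytest.raises(ValueError):
            objective(mini_model, [])

    def test_empty_timepoints_rejected(self, mini_model):
        with pytest.raises(ValueError, match="no timepoints"):
            ExperimentDataset(Condition(), "pB", np.array([]), np.array([]),
                              np.array([]))

    def test_nonpositive_sd_rejected(self, mini_model):
        with pytest.raises(ValueError, match="SD"):
            ExperimentDataset(Condition(), "pB", np.array([5.0]),
                              np.array([1.0]), np.array([0.0]))

    def test_simulation_failure_penalized_not_raised(self, mini_model):
        data = mini_datasets(mini_model)
        cost = objective(mini_model, data, params={"k_act_A": 1e12})
        assert np.isfinite(cost)
        assert cost >= min(PENALTY_COST, 1.0)

    def test_weighted_objective_scales_with_sd(self, mini_model):
        data = mini_datasets(mini_model, sd=0.5)
        bad = {"k_act_B": 3e-4}
        unweighted = objective(mini_model, data, params=bad, weighted=False)
        weighted = objective(mini_model, data, params=bad, weighted=True)
        assert weighted == pytest.approx(unweighted / 0.5, rel=0.3)

    def test_reference_model_self_consistency(self, ref_model):
        """Noise-free synthetic time courses from the reference model give
        (near-)zero objective at the generating parameters."""
        from hgfmet.synth import generate_timecourses

        data = generate_timecourses(ref_model, cv=0.0)
        cost = objective(ref_model, data)
        assert cost < 1e-4


class TestPatternSearch:
    def test_quadratic_bowl_converges(self):
        target = np.array([0.3, -0.2, 0.8, 0.0, -0.5])
        f = lambda x: float(np.sum((x - target) ** 2))
        lo, hi = np.full(5, -2.0), np.full(5, 2.0)
        x, fv, trace, evals = pattern_search(f, np.zeros(5), lo, hi,
                                             mesh_tol=1e-6, max_evals=5000)
        assert np.max(np.abs(x - target)) < 1e-4

    def test_start_at_optimum_stays(self):
        f = lambda x: float(np.sum(x ** 2))
        x, fv, trace, _ = pattern_search(f, np.zeros(3), np.full(3, -1.0),
                                         np.full(3, 1.0), mesh_tol=1e-3)
        assert fv == 0.0 and np.all(x == 0.0)
        assert len(trace) == 1  # no accepted moves

    def test_never_worse_than_start(self):
        rng_vals = {}

        def nasty(x):
            key = tuple(np.round(x, 12))
            if key not in rng_vals:
                rng_vals[key] = float(np.sin(37.0 * np.sum(x)) + np.sum(x ** 4))
            return rng_vals[key]

        x0 = np.array([0.7, -0.7])
        f0 = nasty(x0)
        _, fv, _, _ = pattern_search(nasty, x0, np.full(2, -1.0), np.full(2, 1.0),
                                     max_evals=200)
        assert fv <= f0

    def test_deterministic(self):
        f = lambda x: float(np.sum((x - 0.5) ** 2) + 0.1 * np.sum(np.abs(x)))
        args = (np.zeros(4), np.full(4, -1.0), np.full(4, 1.0))
        r1 = pattern_search(f, *args)
        r2 = pattern_search(f, *args)
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1]

    def test_respects_bounds(self):
        f = lambda x: float(-np.sum(x))  # pushes to the upper bound
        lo, hi = np.zeros(3), np.ones(3)
        x, _, _, _ = pattern_search(f, np.full(3, 0.5), lo, hi, max_evals=500)
        assert np.all(x <= hi + 1e-12)


class TestRecovery:
    def test_noise_free_recovery_within_ten_percent(self):
        truth = build_mini_model()
        data = mini_datasets(truth)
        start = build_mini_model()
        free = ["k_act_A", "k_deact_A", "k_act_B", "k_deact_B"]
        start.set_parameters({n: 2.0 * truth.get_parameter(n) for n in free})
        res = CalibrationModel(start, data, free=free).fit(
            max_evals=4000, mesh_tol=1e-7, step0=0.5)
        # the recovered point matches the generating truth up to the
        # solver-noise floor of the objective (data scale ~600 molecules)
        scale = max(float(ds.means.max()) for ds in data)
        assert res.objective <= objective(truth, data, rtol=1e-6) + 1e-6 * scale
        for name in ("k_act_B", "k_deact_B"):
            assert res.parameters[name] == pytest.approx(
                truth.get_parameter(name), rel=0.10), name

    def test_results_summary_mentions_all_parameters(self, mini_model):
        data = mini_datasets(mini_model)
        res = CalibrationModel(mini_model, data,
                               free=["k_act_B", "k_deact_B"]).fit(max_evals=30)
        text = res.summary()
        assert "k_act_B" in text and "objective" in text
        frame = res.params_frame()
        assert set(frame["parameter"]) == {"k_act_B", "k_deact_B"}

    def test_objective_trace_non_increasing(self, mini_model):
        data = mini_datasets(mini_model)
        start = build_mini_model()
        start.set_parameters({"k_act_B": 5e-4})
        res = CalibrationModel(start, data, free=["k_act_B"]).fit(max_evals=60)
        assert all(a >= b for a, b in zip(res.trace, res.trace[1:]))


class TestInhibitorStrengths:
    def test_recovers_known_strength(self):
        truth = build_mini_model()
        truth.set_parameters({"s_blk": 0.8})
        data = mini_datasets(truth, drug_dose=1.0, condition_id="drug")
        start = build_mini_model()
        start.set_parameters({"s_blk": 0.3})
        est = fit_inhibitor_strengths(start, data, ["s_blk"], max_evals=200)
        assert est["s_blk"] == pytest.approx(0.8, abs=0.05)

    def test_zero_effect_data_gives_zero_strength(self):
        truth = build_mini_model()  # s_blk = 0: drug has no effect
        data = mini_datasets(truth, drug_dose=1.0, condition_id="drug")
        start = build_mini_model()
        start.set_parameters({"s_blk": 0.5})
        est = fit_inhibitor_strengths(start, data, ["s_blk"], max_evals=200)
        assert est["s_blk"] == pytest.approx(0.0, abs=0.05)
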