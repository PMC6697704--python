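"""Resampling statistics, refit ensembles, bands, and identifiability."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_mini_model, mini_datasets
from hgfmet.simulate import Condition
from hgfmet.uncertainty import (
    classify_identifiability,
    confidence_band,
    local_sensitivities,
    lognormal_sigma,
    refit_ensemble,
    resample_datasets,
)


class TestResampling:
    def test_small_cv_limit_returns_means(self, mini_model):
        data = mini_datasets(mini_model)
        reps = resample_datasets(data, n=3, cv=1e-9, seed=0)
        for rep in reps:
            for ds, orig in zip(rep, data):
                np.testing.assert_allclose(ds.means, orig.means, rtol=1e-6)

    def test_empirical_cv_matches_target(self):
        ds = mini_datasets(build_mini_model())[0]
        reps = resample_datasets([ds], n=201, cv=0.10, seed=42)
        draws = np.array([rep[0].means for rep in reps])  # 201 × T
        cv_emp = draws.std(axis=0, ddof=1) / draws.mean(axis=0)
        assert np.all(np.abs(cv_emp - 0.10) < 0.02)

    def test_median_centering(self):
        """Log-normal draws have median at the observed mean."""
        ds = mini_datasets(build_mini_model())[0]
        reps = resample_datasets([ds], n=501, cv=0.2, seed=3)
        draws = np.array([rep[0].means for rep in reps])
        med = np.median(draws, axis=0)
        np.testing.assert_allclose(med, ds.means, rtol=0.03)

    def test_seeded_determinism(self, mini_model):
        data = mini_datasets(mini_model)
        a = resample_datasets(data, n=5, cv=0.1, seed=11)
        b = resample_datasets(data, n=5, cv=0.1, seed=11)
        for ra, rb in zip(a, b):
            for da, db in zip(ra, rb):
                np.testing.assert_array_equal(da.means, db.means)

    def test_nonpositive_mean_rejected(self, mini_model):
        data = mini_datasets(mini_model)
        data[0].means[0] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            resample_datasets(data, n=2, cv=0.1, seed=0)

    def test_sigma_formula(self):
        cv = 0.10
        sigma = lognormal_sigma(cv)
        draws = np.exp(sigma * np.random.default_rng(0).standard_normal(200000))
        assert draws.std() / draws.mean() == pytest.approx(cv, abs=0.005)


class TestRefitEnsemble:
    def test_noise_free_replicates_return_base_fit(self, mini_model):
        data = mini_datasets(mini_model)
        reps = resample_datasets(data, n=4, cv=1e-9, seed=0)
        base = {"k_act_B": 1e-4, "k_deact_B": 0.15}
        ens = refit_ensemble(mini_model, reps, base, free=list(base),
                             max_evals=80)
        assert ens.n_members == 4 and ens.n_failed == 0
        for name, v in base.items():
            np.testing.assert_allclose(ens.parameters[name], v, rtol=0.02)

    def test_refits_respect_decade_bounds(self, mini_model):
        data = mini_datasets(mini_model)
        reps = resample_datasets(data, n=6, cv=0.3, seed=5)
        base = {"k_act_B": 1e-4, "k_deact_B": 0.15}
        ens = refit_ensemble(mini_model, reps, base, free=list(base),
                             max_evals=60)
        for name, v in base.items():
            vals = ens.parameters[name]
            assert np.all(vals >= v / 10 - 1e-15)
            assert np.all(vals <= v * 10 + 1e-15)


class TestConfidenceBand:
    def test_single_member_band_collapses(self, mini_model):
        ens_params = pd.DataFrame([{"k_act_B": 1e-4}])
        from hgfmet.uncertainty import ResampleEnsemble

        ens = ResampleEnsemble(ens_params, seed=0, cv=0.1)
        cond = Condition(output_times=(10.0, 30.0, 60.0), t_end=60.0)
        band = confidence_band(mini_model, ens, "pB", cond)
        np.testing.assert_allclose(band["lower"], band["upper"], rtol=1e-12)

    def test_percentile_ordering(self, mini_model):
        data = mini_datasets(mini_model)
        reps = resample_datasets(data, n=8, cv=0.2, seed=9)
        base = {"k_act_B": 1e-4, "k_deact_B": 0.15}
        ens = refit_ensemble(mini_model, reps, base, free=list(base),
                             max_evals=40)
        cond = Condition(output_times=(10.0, 30.0, 60.0), t_end=60.0)
        band = confidence_band(mini_model, ens, "pB", cond)
        assert np.all(band["lower"] <= band["median"] + 1e-12)
        assert np.all(band["median"] <= band["upper"] + 1e-12)

    def test_empty_ensemble_rejected(self, mini_model):
        from hgfmet.uncertainty import ResampleEnsemble

        ens = ResampleEnsemble(pd.DataFrame(), seed=0, cv=0.1)
        with pytest.raises(ValueError):
            confidence_band(mini_model, ens, "pB", Condition())


class TestLocalSensitivities:
    def test_signs_match_cascade_structure(self, mini_model):
        sens = local_sensitivities(
            mini_model, ["k_act_B", "k_deact_B", "s_blk"],
            outputs=("pB",), times=(30.0,),
            condition=Condition(output_times=(30.0,), t_end=30.0),
        )
        assert sens.loc["k_act_B", "pB@30"] > 0
        assert sens.loc["k_deact_B", "pB@30"] < 0

    def test_parameter_without_path_has_zero_sensitivity(self, ref_model):
        """An undosed drug's binding constant cannot move any output."""
        sens = local_sensitivities(
            ref_model, ["kon_Cabo"], outputs=("pAkt",), times=(120.0,),
        )
        assert abs(sens.loc["kon_Cabo", "pAkt@120"]) < 1e-6

    def test_matches_analytic_slope_on_linear_stage(self, mini_model):
        """At steady state pB* = B_tot * r/(r+d); the log-gradient w.r.t.
        the deactivation rate is -(1 - pB*/B_tot)."""
        cond = Condition(output_times=(400.0,), t_end=400.0)
        sens = local_sensitivities(mini_model, ["k_deact_B"], outputs=("pB",),
                                   times=(400.0,), condition=cond, rtol=1e-9)
        from hgfmet.simulate import basal_state, simulate

        traj = simulate(mini_model, cond, rtol=1e-9)
        frac = traj.readout_at("pB", 400.0) / 2000.0
        assert sens.loc["k_deact_B", "pB@400"] == pytest.approx(-(1 - frac), rel=0.02)

    def test_step_underflow_rejected(self, mini_model):
        with pytest.raises(ValueError):
            local_sensitivities(mini_model, ["k_act_B"], rel_step=0.0)


class TestIdentifiability:
    @staticmethod
    def _make(dfs):
        return [pd.DataFrame(d, index=["p1", "p2"], columns=["o1"]) for d in dfs]

    def test_consistent_sign_is_identifiable(self):
        rng = np.random.default_rng(0)
        mats = self._make([
            np.array([[abs(rng.normal()) + 0.1], [rng.normal()]])
            for _ in range(40)
        ])
        report = classify_identifiability(mats)
        assert bool(report.identifiable["p1"]) is True

    def test_symmetric_sign_distribution_not_identifiable(self):
        rng = np.random.default_rng(1)
        mats = self._make([
            np.array([[0.5], [rng.choice([-1.0, 1.0]) * 0.3]]) for _ in range(40)
        ])
        report = classify_identifiability(mats)
        assert bool(report.identifiable["p2"]) is False

    def test_no_influence_parameters_flagged(self):
        """Parameters whose sensitivities are numerical noise around zero
        (the degenerate/redundant case) fail the sign-consistency rule."""
        rng = np.random.default_rng(2)
        mats = [
            pd.DataFrame(
                {"o1": [1.0 + 0.1 * rng.normal(), 1e-9 * rng.normal()],
                 "o2": [0.5, 1e-9 * rng.normal()]},
                index=["informative", "degenerate"])
            for _ in range(60)
        ]
        report = classify_identifiability(mats)
        assert bool(report.identifiable["informative"]) is True
        assert bool(report.identifiable["degenerate"]) is False
        assert "degenerate" in report.summary()
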