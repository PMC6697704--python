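"""Hill fitting, MuSyC surface recovery, and isobolograms."""

import numpy as np
import pandas as pd
import pytest

from hgfmet.synergy import (
    DoseResponse,
    FitQualityError,
    MusycModel,
    fit_ic50,
    fit_musyc_surface,
    hill_curve,
    isobologram,
    musyc_effect,
)
from hgfmet.synth import generate_musyc_grid

D1 = np.geomspace(1.0, 1000.0, 8)
D2 = np.geomspace(0.1, 100.0, 8)


def make_surface_params(log_alpha2=0.0, beta=0.0, E1=0.30, E2=0.45):
    e_single = min(E1, E2)
    E3 = e_single - beta * (1.0 - e_single)
    return {"E0": 1.0, "E1": E1, "E2": E2, "E3": E3, "h1": 1.1, "h2": 0.9,
            "C1": 60.0, "C2": 8.0, "log_alpha2": log_alpha2}


class TestHillFit:
    def test_recovers_known_parameters(self):
        doses = np.geomspace(1.0, 1000.0, 10)
        effects = hill_curve(doses, 1.0, 0.1, 1.2, 50.0)
        dr = DoseResponse("drug", doses, effects, "pAkt", 120.0, 1000.0)
        fit = fit_ic50(dr)
        assert fit.ic50 == pytest.approx(50.0, rel=0.02)
        assert fit.h == pytest.approx(1.2, rel=0.02)

    def test_dose_scale_equivariance(self):
        doses = np.geomspace(1.0, 1000.0, 10)
        effects = hill_curve(doses, 1.0, 0.2, 1.0, 30.0)
        f1 = fit_ic50(DoseResponse("d", doses, effects, "r", 0.0, 1.0))
        f2 = fit_ic50(DoseResponse("d", 2 * doses, effects, "r", 0.0, 1.0))
        assert f2.C == pytest.approx(2 * f1.C, rel=1e-3)

    def test_flat_curve_rejected(self):
        doses = np.geomspace(1.0, 100.0, 6)
        dr = DoseResponse("d", doses, np.full(6, 0.99), "r", 0.0, 1.0)
        with pytest.raises(FitQualityError, match="flat"):
            fit_ic50(dr)

    def test_unordered_doses_rejected(self):
        with pytest.raises(ValueError):
            DoseResponse("d", np.array([1.0, 1.0]), np.array([1.0, 0.5]),
                         "r", 0.0, 1.0)


class TestMusycFit:
    def test_null_interaction_recovers_zero_synergy(self):
        grid = generate_musyc_grid(make_surface_params(0.0, 0.0, E1=0.3, E2=0.3),
                                   D1, D2, cv=0.0)
        fit = fit_musyc_surface(grid)
        assert abs(fit.log_alpha2) < 0.05
        assert abs(fit.beta) < 0.01

    @pytest.mark.parametrize("log_a2", [-1.0, 0.0, 1.0])
    @pytest.mark.parametrize("beta", [0.0, 0.2, 0.5])
    def test_recovery_lattice(self, log_a2, beta):
        """Known surfaces on 8×8 grids are recovered within 5%."""
        params = make_surface_params(log_a2, beta)
        grid = generate_musyc_grid(params, D1, D2, cv=0.0)
        fit = fit_musyc_surface(grid)
        assert fit.log_alpha2 == pytest.approx(log_a2, abs=0.05)
        assert fit.beta == pytest.approx(beta, abs=0.025)
        for name in ("E1", "E2", "E3", "C1", "C2"):
            truth = params[name] if name in params else None
            assert getattr(fit, name) == pytest.approx(truth, rel=0.05), name

    def test_self_recovery_printed_example(self):
        params = make_surface_params(0.5, 0.2)
        grid = generate_musyc_grid(params, D1, D2, cv=0.0)
        fit = fit_musyc_surface(grid)
        assert fit.log_alpha2 == pytest.approx(0.5, rel=0.01, abs=0.005)
        assert fit.beta == pytest.approx(0.2, rel=0.01, abs=0.005)

    def test_axis_marginals_match_single_drug_curves(self):
        params = make_surface_params(0.3, 0.1)
        grid = generate_musyc_grid(params, D1, D2, cv=0.0)
        fit = fit_musyc_surface(grid)
        axis = grid[grid["d2"] == 0].sort_values("d1")
        pred = fit.effect(axis["d1"].to_numpy(), 0.0)
        np.testing.assert_allclose(pred, axis["effect"].to_numpy(), atol=0.01)

    def test_unit_relabeling_invariance(self):
        """Expressing doses in different units leaves the synergy metrics
        unchanged."""
        params = make_surface_params(0.4, 0.15)
        grid = generate_musyc_grid(params, D1, D2, cv=0.0)
        rescaled = grid.assign(d1=grid["d1"] * 1e-3)  # nM -> µM
        f1, f2 = fit_musyc_surface(grid), fit_musyc_surface(rescaled)
        assert f2.log_alpha2 == pytest.approx(f1.log_alpha2, abs=1e-3)
        assert f2.beta_obs == pytest.approx(f1.beta_obs, abs=1e-9)

    def test_degenerate_grid_rejected(self):
        grid = pd.DataFrame({"d1": [0.0, 1.0, 10.0], "d2": [0.0, 0.0, 0.0],
                             "effect": [1.0, 0.8, 0.5]})
        with pytest.raises(ValueError, match="combination|axes"):
            MusycModel(grid)

    def test_summary_reports_metrics(self):
        grid = generate_musyc_grid(make_surface_params(0.2, 0.1), D1, D2, cv=0.0)
        text = fit_musyc_surface(grid).summary()
        assert "log10(alpha2)" in text and "beta" in text


class TestBetaObs:
    def test_zero_when_combo_equals_best_single(self):
        # E3 exactly at the stronger single-drug plateau
        params = make_surface_params(0.0, 0.0)
        grid = generate_musyc_grid(params, D1 * 100, D2 * 100, cv=0.0)
        fit = fit_musyc_surface(grid)
        assert fit.beta_obs == pytest.approx(0.0, abs=0.02)

    def test_positive_when_combination_deepens_effect(self):
        params = make_surface_params(0.0, 0.3)
        grid = generate_musyc_grid(params, D1 * 100, D2 * 100, cv=0.0)
        fit = fit_musyc_surface(grid)
        assert fit.beta_obs > 0.2


class TestIsobologram:
    @staticmethod
    def loewe_additive(d1, d2, C1=50.0, C2=5.0, E0=1.0, Emax=0.0):
        u = d1 / C1 + d2 / C2
        return E0 + (Emax - E0) * u / (1.0 + u)

    def test_additive_surface_gives_straight_line(self):
        iso = isobologram(self.loewe_additive, 0.5, 1000.0, 100.0)
        # straight isobole: d1/D1 + d2/D2 = 1 with D1, D2 the endpoints
        D1_, D2_ = iso["d1"].iloc[-1], iso["d2"].iloc[0]
        combo = iso["d1"] / D1_ + iso["d2"] / D2_
        np.testing.assert_allclose(combo, 1.0, atol=1e-6)

    def test_endpoints_are_single_drug_doses(self):
        iso = isobologram(self.loewe_additive, 0.5, 1000.0, 100.0)
        assert iso["d1"].iloc[-1] == pytest.approx(50.0, rel=1e-6)
        assert iso["d2"].iloc[0] == pytest.approx(5.0, rel=1e-6)

    def test_synergistic_surface_bows_below_additive_line(self):
        params = make_surface_params(1.0, 0.0, E1=0.0, E2=0.0)
        fit = fit_musyc_surface(generate_musyc_grid(params, D1, D2, cv=0.0))
        iso = isobologram(fit, 0.5, 1000.0, 100.0)
        D1_, D2_ = iso["d1"].iloc[-1], iso["d2"].iloc[0]
        interior = iso.iloc[5:-5]
        additivity = interior["d1"] / D1_ + interior["d2"] / D2_
        assert np.all(additivity < 1.0)

    def test_unreachable_level_raises(self):
        with pytest.raises(ValueError, match="not reachable"):
            isobologram(self.loewe_additive, 0.999, 10.0, 1.0)
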