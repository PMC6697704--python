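"""Structural and dynamical invariants of the pathway network."""

import numpy as np
import pytest

from hgfmet import Condition, build_reference_model, simulate
from hgfmet.network import (
    Modifier,
    ModelStructureError,
    ParameterDef,
    PathwayModel,
    RateEvaluationError,
    ReactionDef,
    SpeciesDef,
)


class TestStructure:
    def test_reference_counts(self, ref_model):
        assert ref_model.n_species == 52
        assert ref_model.n_parameters == 69
        assert len(ref_model.free_parameter_names) == 56

    def test_free_parameters_within_bounds(self, ref_model):
        assert all(p.in_bounds() for p in ref_model.parameters)

    def test_active_species_have_conserved_partner(self, ref_model):
        """Every intracellular active form sits in a conservation group
        together with an inactive form."""
        grouped = {s for g in ref_model.conservation_groups.values() for s in g}
        for sp in ref_model.species:
            if sp.role == "signaling_active" and sp.compartment == "cytosolic":
                assert sp.name in grouped, sp.name
                group = next(g for g in ref_model.conservation_groups.values()
                             if sp.name in g)
                roles = {ref_model.species[ref_model.species_index[x]].role
                         for x in group}
                assert "signaling_inactive" in roles

    def test_unique_names_enforced(self):
        sp = [SpeciesDef("X"), SpeciesDef("X")]
        with pytest.raises(ModelStructureError, match="duplicate"):
            PathwayModel(sp, [], [])

    def test_unknown_reaction_species_rejected(self):
        sp = [SpeciesDef("X")]
        par = [ParameterDef("k", 1.0)]
        rxn = [ReactionDef("r", (("Y", 1),), (), "k")]
        with pytest.raises(ModelStructureError, match="Y"):
            PathwayModel(sp, par, rxn)

    def test_readouts_reference_existing_species(self, ref_model):
        for combo in ref_model.readouts.values():
            for sp in combo:
                assert sp in ref_model.species_index


class TestDerivatives:
    def test_conservation_groups_sum_to_zero(self, ref_model):
        rng = np.random.default_rng(7)
        for _ in range(5):
            state = rng.uniform(0, 1e5, ref_model.n_species)
            dy = ref_model.derivatives(state)
            for members in ref_model.conservation_groups.values():
                idx = [ref_model.species_index[s] for s in members]
                total = np.sum(np.abs(dy[idx]))
                assert abs(np.sum(dy[idx])) < 1e-9 * max(total, 1.0)

    def test_basal_state_is_stationary(self, ref_model, ref_basal):
        dy = ref_model.derivatives(ref_basal)
        scale = np.maximum(np.abs(ref_basal), 1.0)
        assert np.max(np.abs(dy) / scale) < 1e-5

    def test_rate_linear_in_rate_constant(self, ref_model, ref_basal):
        """Mass-action rates scale exactly linearly in their rate constant."""
        j = [r.name for r in ref_model.reactions].index("met_internalization")
        v1 = ref_model.reaction_rates(ref_basal)[j]
        doubled = ref_model.copy()
        doubled.set_parameters({"kint_Met": 2 * ref_model.get_parameter("kint_Met")})
        v2 = doubled.reaction_rates(ref_basal)[j]
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_nonfinite_rate_identifies_reaction(self, mini_model):
        mini_model.set_parameters({"k_act_A": np.inf})
        state = mini_model.initial_state()
        state[mini_model.species_index["HGF"]] = 1.0
        with pytest.raises(RateEvaluationError, match="act_A"):
            mini_model.derivatives(state)


class TestSimulation:
    def test_unstimulated_baseline_flat(self, ref_model, ref_basal):
        cond = Condition(hgf_dose=0.0, output_times=(0.0, 30.0, 60.0, 120.0))
        traj = simulate(ref_model, cond, y_basal=ref_basal)
        for r in ("pAkt", "pERK"):
            vals = traj.readouts[r]
            assert np.ptp(vals) < 0.02 * max(np.max(vals), 1.0)

    def test_trajectory_conservation(self, ref_model, hgf_trajectory):
        for members in ref_model.conservation_groups.values():
            idx = [ref_model.species_index[s] for s in members]
            totals = hgf_trajectory.state[:, idx].sum(axis=1)
            assert np.max(np.abs(totals - totals[0])) / totals[0] < 1e-6

    def test_trajectory_nonnegative(self, hgf_trajectory):
        assert np.min(hgf_trajectory.state) > -1e-6

    def test_condition_validation(self):
        with pytest.raises(ValueError):
            Condition(hgf_dose=-1.0)
        with pytest.raises(ValueError):
            Condition(drug_doses={"Sorafenib": -5.0})
        with pytest.raises(ValueError):
            Condition(t_end=60.0, output_times=(0.0, 120.0))

    def test_readout_interpolation(self, hgf_trajectory):
        v15 = hgf_trajectory.readout_at("pAkt", 15.0)
        assert v15 == pytest.approx(hgf_trajectory.readouts["pAkt"][3])

    def test_hgf_dose_monotone_at_steady_state(self, ref_model, ref_basal):
        """More ligand gives more steady-state signal."""
        vals = []
        for dose in (5.0, 20.0, 80.0):
            cond = Condition(hgf_dose=dose, output_times=(120.0,))
            traj = simulate(ref_model, cond, y_basal=ref_basal)
            vals.append(traj.readout_at("pAkt", 120.0))
        assert vals[0] < vals[1] < vals[2]


class TestKnockoutScenario:
    def test_integrin_loss_hits_pakt_harder_than_perk(self, ref_model, hgf_condition):
        from hgfmet import integrin_knockout_scenario

        base, ko = integrin_knockout_scenario(ref_model, hgf_condition)
        pakt_drop = 1 - ko.readout_at("pAkt", 120) / base.readout_at("pAkt", 120)
        perk_drop = 1 - ko.readout_at("pERK", 120) / base.readout_at("pERK", 120)
        assert ko.readout_at("pAkt", 120) < base.readout_at("pAkt", 120)
        assert perk_drop < pakt_drop

    def test_knockout_idempotent_without_association(self, ref_model, ref_basal):
        from hgfmet import integrin_knockout_scenario

        no_assoc = ref_model.copy()
        no_assoc.set_parameters({"kon_Met_Itg": 0.0})
        cond = Condition(output_times=(0.0, 60.0, 120.0))
        base, ko = integrin_knockout_scenario(no_assoc, cond)
        for r in ("pAkt", "pERK", "pMet_total"):
            np.testing.assert_allclose(base.readouts[r], ko.readouts[r], rtol=1e-9)

    def test_equal_trafficking_removes_knockout_difference(self, ref_model):
        """With Met–Itg trafficking rates set equal to free-Met rates the
        integrin association no longer protects the receptor."""
        from hgfmet import integrin_knockout_scenario

        flat = ref_model.copy()
        flat.set_parameters({
            "kint_pMetItg": flat.get_parameter("kint_pMet"),
            "krec_pMetItg": flat.get_parameter("krec_pMet"),
            "kdeg_pMetItg_i": flat.get_parameter("kdeg_pMet_i"),
        })
        cond = Condition(output_times=(120.0,))
        base, ko = integrin_knockout_scenario(flat, cond)
        diff = abs(1 - ko.readout_at("pAkt", 120) / base.readout_at("pAkt", 120))
        assert diff < 0.01


class TestPercentInhibition:
    def test_zero_dose_gives_zero(self, ref_model):
        from hgfmet import percent_inhibition

        cond = Condition(output_times=(120.0,))
        val = percent_inhibition(ref_model, cond, cond, "pAkt", 120.0)
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_saturating_cabozantinib_near_complete(self, ref_model, ref_basal):
        from hgfmet import percent_inhibition

        ref = Condition(output_times=(120.0,))
        drug = ref.with_doses(Cabozantinib=1000.0)
        val = percent_inhibition(ref_model, drug, ref, "pAkt", 120.0,
                                 y_basal=ref_basal)
        assert val > 90.0

    def test_sorafenib_raises_steady_state_pakt(self, ref_model, ref_basal):
        from hgfmet import percent_inhibition

        ref = Condition(output_times=(120.0,))
        drug = ref.with_doses(Sorafenib=1000.0)
        val = percent_inhibition(ref_model, drug, ref, "pAkt", 120.0,
                                 y_basal=ref_basal)
        assert val <= 0.0

    def test_zero_reference_raises(self, mini_model):
        from hgfmet import percent_inhibition

        cond = Condition(hgf_dose=0.0, output_times=(10.0,))
        with pytest.raises(ZeroDivisionError):
            percent_inhibition(mini_model, cond, cond, "pB", 10.0)
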