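import numpy as np
import pytest

from hgfmet import Condition, basal_state, build_reference_model, simulate
from hgfmet.network import Modifier, ParameterDef, PathwayModel, ReactionDef, SpeciesDef

STANDARD_TIMES = tuple(float(t) for t in (0, 5, 10, 15, 30, 60, 90, 120))


@pytest.fixture(scope="session")
def ref_model():
    return build_reference_model()


@pytest.fixture(scope="session")
def ref_basal(ref_model):
    return basal_state(ref_model)


@pytest.fixture(scope="session")
def hgf_condition():
    return Condition(hgf_dose=40.0, output_times=STANDARD_TIMES)


@pytest.fixture(scope="session")
def hgf_trajectory(ref_model, hgf_condition, ref_basal):
    return simulate(ref_model, hgf_condition, y_basal=ref_basal)


def build_mini_model() -> PathwayModel:
    """Two-stage ligand-driven cascade used for fast fitting tests.

    HGF (clamped, nM) activates A; active A activates B; a clamped drug
    species D blocks B activation with strength s_blk.  Steady state is
    reached within ~20 min and one simulation costs milliseconds.
    """
    species = [
        SpeciesDef("HGF", "extracellular", "ligand", 0.0, constant=True),
        SpeciesDef("A", "cytosolic", "signaling_inactive", 1000.0),
        SpeciesDef("aA", "cytosolic", "signaling_active", 0.0),
        SpeciesDef("B", "cytosolic", "signaling_inactive", 2000.0),
        SpeciesDef("pB", "cytosolic", "signaling_active", 0.0),
        SpeciesDef("D", "extracellular", "drug", 0.0, constant=True),
    ]
    parameters = [
        ParameterDef("k_act_A", 0.6, True, (0.006, 60.0)),
        ParameterDef("k_deact_A", 0.2, True, (0.002, 20.0)),
        ParameterDef("k_act_B", 1e-4, True, (1e-6, 1e-2)),
        ParameterDef("k_deact_B", 0.15, True, (0.0015, 15.0)),
        ParameterDef("s_blk", 0.0, True, (0.0, 1.0)),
    ]
    reactions = [
        ReactionDef("act_A", (("A", 1),), (("aA", 1),), "k_act_A",
                    (Modifier("mass", ("HGF",)),)),
        ReactionDef("deact_A", (("aA", 1),), (("A", 1),), "k_deact_A"),
        ReactionDef("act_B", (("B", 1),), (("pB", 1),), "k_act_B",
                    (Modifier("mass", ("aA",)),
                     Modifier("block", ("D",), weight_param="s_blk"))),
        ReactionDef("deact_B", (("pB", 1),), (("B", 1),), "k_deact_B"),
    ]
    return PathwayModel(
        species, parameters, reactions,
        conservation_groups={"A": ("A", "aA"), "B": ("B", "pB")},
        readouts={"aA": {"aA": 1.0}, "pB": {"pB": 1.0}},
        name="mini_cascade",
    )


@pytest.fixture()
def mini_model():
    return build_mini_model()


def mini_datasets(model, times=(5.0, 15.0, 30.0, 60.0), readouts=("aA", "pB"),
                  drug_dose=0.0, condition_id="hgf", sd=0.05, rtol=1e-6):
    """Noise-free datasets simulated from the mini model (absolute scale).

    The default solver tolerance matches the calibration objective so that
    the generating parameters are an exact zero of the objective.
    """
    from hgfmet.calibrate import ExperimentDataset

    cond = Condition(hgf_dose=40.0, output_times=times, t_end=max(times),
                     drug_doses={"D": drug_dose} if drug_dose else {})
    traj = simulate(model, cond, rtol=rtol)
    out = []
    for r in readouts:
        means = np.array([traj.readout_at(r, t) for t in times])
        out.append(ExperimentDataset(cond, r, np.array(times), means,
                                     np.full(len(times), sd),
                                     condition_id=condition_id,
                                     normalization="none"))
    return out
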