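"""Synthetic data generation with known ground truth.

Every pipeline input can be generated here: noisy normalized time
courses in the calibration schema (multiplicative log-normal noise on
model trajectories, mean ± SD over pseudo-replicates), two-drug MuSyC
response grids from known surface parameters, and virtual-patient
cohorts of per-protein log2 fold changes.  All generators are pure
functions of their arguments and a mandatory seed.

The default calibration suite mirrors a feedback-resolving experimental
design: HGF alone, HGF + MEK inhibitor, HGF + PDK1 inhibitor, and the
double inhibition, each read out at pAkt/pMEK/pERK/pRSK/ppRSK, plus
phospho-Met under HGF alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibrate import ExperimentDataset
from .cohort import PatientProfile
from .network import PathwayModel
from .reference import COHORT_PROTEINS
from .simulate import Condition, basal_state, simulate
from .synergy import musyc_effect
from .uncertainty import lognormal_sigma

__all__ = [
    "default_calibration_conditions",
    "generate_timecourses",
    "generate_cohort",
    "generate_musyc_grid",
]

DEFAULT_TIMES = (0.0, 5.0, 10.0, 15.0, 30.0, 60.0, 90.0, 120.0)
SIGNALING_READOUTS = ("pAkt", "pMEK", "pERK", "pRSK", "ppRSK")


def default_calibration_conditions(times: tuple[float, ...] = DEFAULT_TIMES
                                   ) -> dict[str, tuple[Condition, tuple[str, ...]]]:
    """Condition id -> (condition, readouts) for the calibration design."""
    base = dict(hgf_dose=40.0, output_times=times, t_end=max(times))
    return {
        "hgf": (Condition(**base), SIGNALING_READOUTS + ("pMet_total",)),
        "hgf_meki": (Condition(drug_doses={"MEKi": 1.0}, **base), SIGNALING_READOUTS),
        "hgf_pdk1i": (Condition(drug_doses={"PDK1i": 1.0}, **base), SIGNALING_READOUTS),
        "hgf_meki_pdk1i": (
            Condition(drug_doses={"MEKi": 1.0, "PDK1i": 1.0}, **base),
            SIGNALING_READOUTS,
        ),
    }


def generate_timecourses(model: PathwayModel,
                         truth: dict[str, float] | None = None,
                         conditions: dict[str, tuple[Condition, tuple[str, ...]]] | None = None,
                         cv: float = 0.10, n_rep: int = 3, seed: int = 0,
                         rtol: float = 1e-6) -> list[ExperimentDataset]:
    """Simulate, normalize to the HGF-only control maximum, add
    multiplicative log-normal noise, and summarize as mean ± SD over
    ``n_rep`` pseudo-replicates.

    ``cv = 0`` returns the noise-free normalized curves with a nominal SD.
    """
    rng = np.random.default_rng(seed)
    work = model.copy()
    if truth:
        work.set_parameters(truth)
    conditions = conditions or default_calibration_conditions()
    yb = basal_state(work, rtol=rtol)
    trajs = {cid: simulate(work, cond, rtol=rtol, y_basal=yb)
             for cid, (cond, _) in conditions.items()}
    control = trajs.get("hgf") or next(iter(trajs.values()))
    datasets = []
    for cid, (cond, readouts) in conditions.items():
        for readout in readouts:
            sim = trajs[cid].readouts[readout]
            denom = float(np.max(control.readouts[readout]))
            norm = sim / denom if denom > 0 else sim
            times = trajs[cid].times
            if cv > 0:
                sigma = lognormal_sigma(cv)
                reps = norm[None, :] * np.exp(
                    sigma * rng.standard_normal((n_rep, len(norm))))
                means = reps.mean(axis=0)
                sds = reps.std(axis=0, ddof=1) if n_rep > 1 else np.full_like(means, cv)
                sds = np.maximum(sds, 1e-6)
            else:
                means = norm.copy()
                sds = np.maximum(np.abs(means) * 0.10, 1e-6)
            keep = means > 0
            datasets.append(ExperimentDataset(
                cond, readout, times[keep], means[keep], sds[keep],
                condition_id=cid,
            ))
    return datasets


def generate_cohort(n: int = 50, log2fc_mean: float = 0.0, log2fc_sd: float = 1.0,
                    seed: int = 0, proteins: tuple[str, ...] | None = None
                    ) -> list[PatientProfile]:
    """Virtual cohort: independent normal log2 fold changes per protein."""
    if n < 1:
        raise ValueError("need at least one patient")
    rng = np.random.default_rng(seed)
    proteins = tuple(COHORT_PROTEINS) if proteins is None else proteins
    profiles = []
    for i in range(n):
        draws = log2fc_mean + log2fc_sd * rng.standard_normal(len(proteins))
        profiles.append(PatientProfile(
            f"patient_{i+1:03d}", dict(zip(proteins, draws))))
    return profiles


def generate_musyc_grid(params: dict[str, float], doses1: np.ndarray,
                        doses2: np.ndarray, cv: float = 0.0,
                        seed: int = 0) -> pd.DataFrame:
    """Evaluate a known MuSyC surface on a (0 + doses1) × (0 + doses2)
    grid, optionally with multiplicative log-normal noise.

    ``params`` holds E0, E1, E2, E3, h1, h2, C1, C2 and either ``alpha2``
    or ``log_alpha2``.
    """
    p = dict(params)
    if "alpha2" not in p:
        p["alpha2"] = 10.0 ** p.pop("log_alpha2")
    rng = np.random.default_rng(seed)
    rows = []
    for a in np.concatenate([[0.0], np.asarray(doses1, float)]):
        for b in np.concatenate([[0.0], np.asarray(doses2, float)]):
            e = float(musyc_effect(a, b, p["E0"], p["E1"], p["E2"], p["E3"],
                                   p["h1"], p["h2"], p["C1"], p["C2"], p["alpha2"]))
            if cv > 0:
                e *= float(np.exp(lognormal_sigma(cv) * rng.standard_normal()))
            rows.append((float(a), float(b), e))
    return pd.DataFrame(rows, columns=["d1", "d2", "effect"])
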