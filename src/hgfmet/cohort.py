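"""Virtual patients: fold-change scaling of protein abundances.

A patient profile is a per-protein log2 fold change (tumor vs. matched
normal).  Scaling keeps every reaction rate constant and multiplies the
protein's total abundance — the initial amount of its conservation-group
holder and, for the surface receptors, the synthesis rate — by
2**log2FC.  Missing proteins are treated as unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import PathwayModel
from .reference import COHORT_PROTEINS
from .simulate import Condition, basal_state, simulate

__all__ = [
    "PatientProfile",
    "scale_model",
    "cohort_monotherapy",
    "cohort_synergy",
    "REFERENCE_DOSES",
    "profiles_to_frame",
    "frame_to_profiles",
]

#: Monotherapy reference doses (nM): the top of each drug's dose range.
REFERENCE_DOSES = {
    "AXT050": 1e5,
    "Cabozantinib": 1000.0,
    "Rilotumumab": 10.0,
    "Sorafenib": 1000.0,
}


@dataclass
class PatientProfile:
    patient_id: str
    log2fc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prot, fc in self.log2fc.items():
            if not np.isfinite(fc):
                raise ValueError(f"{self.patient_id}: non-finite fold change for {prot}")


def profiles_to_frame(profiles: list[PatientProfile]) -> pd.DataFrame:
    """Cohort table: rows = proteins, columns = patients."""
    proteins = sorted({p for prof in profiles for p in prof.log2fc})
    data = {prof.patient_id: [prof.log2fc.get(p, 0.0) for p in proteins]
            for prof in profiles}
    return pd.DataFrame(data, index=proteins)


def frame_to_profiles(frame: pd.DataFrame) -> list[PatientProfile]:
    return [
        PatientProfile(str(col), {p: float(frame.loc[p, col]) for p in frame.index})
        for col in frame.columns
    ]


def scale_model(reference: PathwayModel, profile: PatientProfile) -> PathwayModel:
    """Patient-specific model: abundances scaled, rate constants untouched."""
    unknown = sorted(set(profile.log2fc) - set(COHORT_PROTEINS))
    if unknown:
        raise KeyError(
            f"unknown proteins {unknown}; valid: {sorted(COHORT_PROTEINS)}"
        )
    model = reference.copy()
    for prot, fc in profile.log2fc.items():
        factor = 2.0 ** fc
        spec = COHORT_PROTEINS[prot]
        for sp in spec["species"]:
            i = model.species_index[sp]
            model.set_initial({sp: model.species[i].initial_amount * factor})
        for param in spec["synthesis"]:
            model.set_parameters({param: model.get_parameter(param) * factor})
    return model


def cohort_monotherapy(reference: PathwayModel, profiles: list[PatientProfile],
                       drugs: dict[str, float] | None = None,
                       readouts: tuple[str, ...] = ("pAkt", "pERK"),
                       t: float = 120.0, hgf_dose: float = 40.0,
                       rtol: float = 1e-6) -> pd.DataFrame:
    """Percent inhibition of each readout per patient per drug at time t.

    Patients whose simulations fail are flagged with NaN rows rather than
    aborting the cohort.
    """
    drugs = dict(REFERENCE_DOSES) if drugs is None else drugs
    rows = []
    for prof in profiles:
        model = scale_model(reference, prof)
        rec: dict[str, float | str] = {"patient": prof.patient_id}
        try:
            yb = basal_state(model, rtol=rtol)
            cond0 = Condition(hgf_dose=hgf_dose, output_times=(t,), t_end=t)
            ref_traj = simulate(model, cond0, rtol=rtol, y_basal=yb)
            for drug, dose in drugs.items():
                cond = cond0.with_doses(**{drug: dose})
                traj = simulate(model, cond, rtol=rtol, y_basal=yb)
                for r in readouts:
                    denom = ref_traj.readout_at(r, t)
                    rec[f"{drug}:{r}"] = 100.0 * (1.0 - traj.readout_at(r, t) / denom)
        except Exception:
            for drug in drugs:
                for r in readouts:
                    rec.setdefault(f"{drug}:{r}", np.nan)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("patient")


def cohort_synergy(reference: PathwayModel, profiles: list[PatientProfile],
                   drug_pairs: list[tuple[str, str]] | None = None,
                   readouts: tuple[str, ...] = ("pAkt", "pERK"),
                   t: float = 120.0, n_doses: int = 5,
                   rtol: float = 1e-6) -> pd.DataFrame:
    """Per-patient MuSyC synergy metrics for drug pairs.

    Drug 1 of every pair is AXT050 by convention.  Per-patient fit
    failures are flagged with NaNs.
    """
    from .synergy import MusycModel, default_grid, response_grid

    if drug_pairs is None:
        drug_pairs = [("AXT050", "Sorafenib"), ("AXT050", "Cabozantinib"),
                      ("AXT050", "Rilotumumab")]
    rows = []
    for prof in profiles:
        model = scale_model(reference, prof)
        rec: dict[str, float | str] = {"patient": prof.patient_id}
        for d1, d2 in drug_pairs:
            for r in readouts:
                key = f"{d1}+{d2}:{r}"
                try:
                    grid = response_grid(
                        model, d1, d2, r, t=t,
                        doses1=default_grid(d1, n_doses),
                        doses2=default_grid(d2, n_doses), rtol=rtol,
                    )
                    fit = MusycModel(grid).fit()
                    rec[f"{key}:log_alpha2"] = fit.log_alpha2
                    rec[f"{key}:beta_obs"] = fit.beta_obs
                except Exception:
                    rec[f"{key}:log_alpha2"] = np.nan
                    rec[f"{key}:beta_obs"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("patient")
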