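"""Drug mechanisms as condition/model transformations.

Four mechanisms are modeled:

* **AXT050** (integrin dissociator): binds α5β1 and strips it out of
  Met-containing complexes; mass-action binding with the reference
  affinity, applied by dosing the ``AXT050`` species.
* **Cabozantinib** (receptor binder): occupies Met so that HGF cannot
  activate it; the bound receptor keeps constitutive trafficking.
* **Rilotumumab** (ligand depletion): with antibody in excess, free
  ligand follows the closed form HGF_free = HGF_total * Kd / (Kd + dose);
  the condition's effective HGF dose is reduced accordingly at simulation
  time.
* **Node-output inhibitors** (Met, PDK1, MEK, PI3K, ERK node inhibitors
  and sorafenib on Raf): multiply the rate laws leaving the node by
  1 - s * dose / (dose + K). The calibration-time inhibitors use a
  vanishing K, i.e. strength-scaled full blockade at any nonzero dose;
  sorafenib's K is a model parameter so dose-response curves are
  meaningful.

Because the reference network already carries every drug species and its
reactions, applying a drug amounts to setting its clamped dose — which
makes perturbations trivially composable and reversible.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import ModelStructureError, PathwayModel
from .simulate import Condition

__all__ = [
    "DrugSpec",
    "DRUGS",
    "NODE_INHIBITORS",
    "apply_axt050",
    "apply_cabozantinib",
    "apply_rilotumumab",
    "apply_node_inhibitor",
    "remove_drug",
]


@dataclass(frozen=True)
class DrugSpec:
    name: str
    mechanism: str  # integrin_dissociator | receptor_binder | ligand_depletion | node_output_inhibition
    target: str
    dose_range: tuple[float, float]  # nM
    affinity: float | None = None  # Kd in nM, binders only
    strength_param: str | None = None  # node inhibitors only

    def __post_init__(self) -> None:
        if self.affinity is not None and self.affinity <= 0:
            raise ValueError(f"{self.name}: affinity must be positive")
        lo, hi = self.dose_range
        if not (0 < lo < hi):
            raise ValueError(f"{self.name}: dose range must be positive and ordered")


#: Therapeutic dose ranges (nM): 1–1000 for sorafenib and cabozantinib,
#: 0.01–10 for rilotumumab; AXT050 is a peptide dosed in the µM range.
DRUGS = {
    "AXT050": DrugSpec("AXT050", "integrin_dissociator", "Itg", (1e2, 1e5),
                       affinity=1e4),
    "Cabozantinib": DrugSpec("Cabozantinib", "receptor_binder", "Met", (1.0, 1000.0),
                             affinity=1.3),
    "Rilotumumab": DrugSpec("Rilotumumab", "ligand_depletion", "HGF", (0.01, 10.0),
                            affinity=0.5),
    "Sorafenib": DrugSpec("Sorafenib", "node_output_inhibition", "Raf", (1.0, 1000.0),
                          strength_param="s_sor"),
}

NODE_INHIBITORS = {
    "Met": ("Meti", "s_Met"),
    "PDK1": ("PDK1i", "s_PDK1"),
    "MEK": ("MEKi", "s_MEK"),
    "PI3K": ("PI3Ki", "s_PI3K"),
    "ERK": ("ERKi", "s_ERK"),
    "Raf": ("Sorafenib", "s_sor"),
}


def _require_species(model: PathwayModel, name: str) -> None:
    if name not in model.species_index:
        raise ModelStructureError(
            f"model has no {name!r} species; build drug reactions first"
        )


def apply_axt050(model: PathwayModel, condition: Condition, dose: float) -> Condition:
    """Dose the integrin-dissociating peptide; dose 0 leaves the condition
    unchanged."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    _require_species(model, "AXT050")
    return condition.with_doses(AXT050=float(dose))


def apply_cabozantinib(model: PathwayModel, condition: Condition, dose: float) -> Condition:
    if dose < 0:
        raise ValueError("dose must be non-negative")
    _require_species(model, "Cabozantinib")
    return condition.with_doses(Cabozantinib=float(dose))


def apply_rilotumumab(dose: float, hgf_total: float, kd: float) -> float:
    """Free HGF (nM) under excess-antibody equilibrium."""
    if min(dose, hgf_total) < 0:
        raise ValueError("dose and ligand must be non-negative")
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return hgf_total * kd / (kd + dose)


def apply_node_inhibitor(model: PathwayModel, condition: Condition, node: str,
                         dose: float = 1.0, strength: float | None = None) -> Condition:
    """Dose the output inhibitor of a signaling node.

    ``strength`` optionally overrides the inhibition-strength parameter in
    place on the model (strength 0 restores the unperturbed behavior).
    """
    if node not in NODE_INHIBITORS:
        raise ModelStructureError(
            f"unknown node {node!r}; valid nodes: {sorted(NODE_INHIBITORS)}"
        )
    species, sparam = NODE_INHIBITORS[node]
    _require_species(model, species)
    if strength is not None:
        if not 0 <= strength <= 1:
            raise ValueError("inhibition strength must lie in [0, 1]")
        model.set_parameters({sparam: strength})
    return condition.with_doses(**{species: float(dose)})


def remove_drug(condition: Condition, drug: str) -> Condition:
    """Reset a drug's dose to zero (perturbations are reversible)."""
    return condition.with_doses(**{drug: 0.0})
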