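"""Reaction-network container and compiled ODE right-hand side.

The pathway is represented as mass-action reactions whose rates may be
scaled by *modifier* factors — the mechanism used for feedback loops,
crosstalk, and node-level drug inhibition.  A reaction rate is

    v = k * prod(reactant_i ** stoich_i) * prod(modifier factors)

with modifier kinds:

``mass``
    factor = sum(X_j) — a catalyst/driver appearing in the rate but not
    consumed (e.g. Gab1 activation driven by the total phospho-Met pool).
``scaled``
    factor = sum(X_j) / scale — a normalized driver, so the rate constant
    keeps first-order units (e.g. Akt activation by the PIP3 fraction).
``activate``
    factor = 1 + w * sum(X_j) / scale — positive feedback (w is a model
    parameter).
``inhibit``
    factor = 1 / (1 + w * sum(X_j) / scale) — negative feedback.
``block``
    factor = 1 - s * D / (D + K) — node-output inhibition by a drug whose
    dose is the (clamped) amount D of a drug species; s is an inhibition
    strength parameter in [0, 1] and K the half-blocking dose (a parameter
    for dose-resolved drugs such as sorafenib, or a small constant for the
    calibration-time node inhibitors, which act as full blockade scaled by
    s at any nonzero dose).

Species amounts are molecules/cell for cellular species and nM for
extracellular ligand and drugs; extracellular species are clamped
(constant) because the medium acts as an effectively infinite reservoir.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SpeciesDef",
    "ParameterDef",
    "Modifier",
    "ReactionDef",
    "PathwayModel",
    "ModelStructureError",
    "RateEvaluationError",
]

COMPARTMENTS = ("extracellular", "surface", "endosomal", "cytosolic")
ROLES = (
    "ligand",
    "receptor",
    "integrin",
    "complex",
    "signaling_inactive",
    "signaling_active",
    "drug",
)
MODIFIER_KINDS = ("mass", "scaled", "activate", "inhibit", "block")


class ModelStructureError(ValueError):
    """A species/parameter/reaction referenced in the model does not exist
    or violates a structural invariant."""


class RateEvaluationError(RuntimeError):
    """A rate law evaluated to NaN/Inf; carries the offending reaction."""


@dataclass
class SpeciesDef:
    name: str
    compartment: str = "cytosolic"
    role: str = "signaling_inactive"
    initial_amount: float = 0.0
    constant: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelStructureError(
                f"unknown compartment {self.compartment!r} for species {self.name}"
            )
        if self.role not in ROLES:
            raise ModelStructureError(f"unknown role {self.role!r} for species {self.name}")
        if self.initial_amount < 0:
            raise ModelStructureError(f"negative initial amount for species {self.name}")


@dataclass
class ParameterDef:
    name: str
    value: float
    free: bool = False
    bounds: tuple[float, float] | None = None

    def in_bounds(self) -> bool:
        if not self.free or self.bounds is None:
            return True
        lo, hi = self.bounds
        return lo <= self.value <= hi


@dataclass
class Modifier:
    kind: str
    species: tuple[str, ...]
    weight_param: str | None = None  # parameter name for w / s
    scale: float = 1.0
    k_param: str | None = None  # parameter name for the block K
    k_value: float = 1e-3  # fixed K when k_param is None (full blockade)

    def __post_init__(self) -> None:
        if self.kind not in MODIFIER_KINDS:
            raise ModelStructureError(f"unknown modifier kind {self.kind!r}")
        if isinstance(self.species, str):
            self.species = (self.species,)
        else:
            self.species = tuple(self.species)


@dataclass
class ReactionDef:
    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_param: str
    modifiers: tuple[Modifier, ...] = ()

    def __post_init__(self) -> None:
        self.reactants = tuple((s, int(n)) for s, n in self.reactants)
        self.products = tuple((s, int(n)) for s, n in self.products)
        self.modifiers = tuple(self.modifiers)


@dataclass
class _Compiled:
    """Index arrays for vectorized rate evaluation."""

    stoich: np.ndarray  # (n_species, n_reactions), net stoichiometry
    k_idx: np.ndarray  # (n_reactions,) parameter index of the rate constant
    react_rxn: np.ndarray  # flattened reactant slots
    react_sp: np.ndarray
    react_exp: np.ndarray
    mod_matrix: np.ndarray  # (n_mod, n_species) 0/1 summation matrix
    mod_rxn: np.ndarray  # (n_mod,) reaction index per modifier
    mod_kind: np.ndarray  # (n_mod,) integer code
    mod_w_idx: np.ndarray  # (n_mod,) weight parameter index (-1 -> 1.0)
    mod_scale: np.ndarray  # (n_mod,)
    mod_k_idx: np.ndarray  # (n_mod,) K parameter index (-1 -> fixed)
    mod_k_fixed: np.ndarray  # (n_mod,)
    dynamic_mask: np.ndarray  # (n_species,) True where the ODE applies


_KIND_CODE = {k: i for i, k in enumerate(MODIFIER_KINDS)}


class PathwayModel:
    """A reaction network with conservation groups and named readouts.

    Parameters
    ----------
    species, parameters, reactions
        The structural definition; all cross-references are validated.
    conservation_groups
        Mapping of group name to the species whose summed amount is
        dynamically invariant (interconversion only).
    readouts
        Mapping of readout name to a ``{species: weight}`` linear
        combination.
    """

    def __init__(
        self,
        species: Sequence[SpeciesDef],
        parameters: Sequence[ParameterDef],
        reactions: Sequence[ReactionDef],
        conservation_groups: dict[str, tuple[str, ...]] | None = None,
        readouts: dict[str, dict[str, float]] | None = None,
        name: str = "pathway",
    ) -> None:
        self.name = name
        self.species = list(species)
        self.parameters = list(parameters)
        self.reactions = list(reactions)
        self.conservation_groups = {
            k: tuple(v) for k, v in (conservation_groups or {}).items()
        }
        self.readouts = {k: dict(v) for k, v in (readouts or {}).items()}
        self._validate()
        self.species_index = {s.name: i for i, s in enumerate(self.species)}
        self.parameter_index = {p.name: i for i, p in enumerate(self.parameters)}
        self._compiled: _Compiled | None = None

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ModelStructureError(f"duplicate species names: {dup}")
        pnames = [p.name for p in self.parameters]
        if len(set(pnames)) != len(pnames):
            dup = sorted({n for n in pnames if pnames.count(n) > 1})
            raise ModelStructureError(f"duplicate parameter names: {dup}")
        sset, pset = set(names), set(pnames)
        for rxn in self.reactions:
            for sp, _ in rxn.reactants + rxn.products:
                if sp not in sset:
                    raise ModelStructureError(
                        f"reaction {rxn.name}: unknown species {sp!r}"
                    )
            if rxn.rate_param not in pset:
                raise ModelStructureError(
                    f"reaction {rxn.name}: unknown rate parameter {rxn.rate_param!r}"
                )
            for mod in rxn.modifiers:
                for sp in mod.species:
                    if sp not in sset:
                        raise ModelStructureError(
                            f"reaction {rxn.name}: unknown modifier species {sp!r}"
                        )
                for pname in (mod.weight_param, mod.k_param):
                    if pname is not None and pname not in pset:
                        raise ModelStructureError(
                            f"reaction {rxn.name}: unknown modifier parameter {pname!r}"
                        )
        for gname, members in self.conservation_groups.items():
            for sp in members:
                if sp not in sset:
                    raise ModelStructureError(
                        f"conservation group {gname}: unknown species {sp!r}"
                    )
        for rname, combo in self.readouts.items():
            for sp in combo:
                if sp not in sset:
                    raise ModelStructureError(f"readout {rname}: unknown species {sp!r}")

    # -- convenience -------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    @property
    def free_parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters if p.free]

    def parameter_vector(self) -> np.ndarray:
        return np.array([p.value for p in self.parameters], dtype=float)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def get_parameter(self, name: str) -> float:
        return self.parameters[self.parameter_index[name]].value

    def set_parameters(self, updates: dict[str, float]) -> None:
        for name, value in updates.items():
            if name not in self.parameter_index:
                raise ModelStructureError(f"unknown parameter {name!r}")
            i = self.parameter_index[name]
            self.parameters[i] = replace(self.parameters[i], value=float(value))

    def set_initial(self, updates: dict[str, float]) -> None:
        for name, value in updates.items():
            if name not in self.species_index:
                raise ModelStructureError(f"unknown species {name!r}")
            i = self.species_index[name]
            self.species[i] = replace(self.species[i], initial_amount=float(value))

    def copy(self) -> "PathwayModel":
        return PathwayModel(
            [replace(s) for s in self.species],
            [replace(p) for p in self.parameters],
            [
                ReactionDef(
                    r.name,
                    r.reactants,
                    r.products,
                    r.rate_param,
                    tuple(replace(m) for m in r.modifiers),
                )
                for r in self.reactions
            ],
            dict(self.conservation_groups),
            {k: dict(v) for k, v in self.readouts.items()},
            name=self.name,
        )

    def group_total(self, group: str, state: np.ndarray) -> float:
        idx = [self.species_index[s] for s in self.conservation_groups[group]]
        return float(np.sum(state[idx]))

    def readout_matrix(self) -> tuple[list[str], np.ndarray]:
        names = list(self.readouts)
        R = np.zeros((len(names), self.n_species))
        for i, rname in enumerate(names):
            for sp, w in self.readouts[rname].items():
                R[i, self.species_index[sp]] = w
        return names, R

    # -- compiled RHS ------------------------------------------------------

    def compile(self) -> _Compiled:
        if self._compiled is not None:
            return self._compiled
        n_s, n_r = self.n_species, len(self.reactions)
        stoich = np.zeros((n_s, n_r))
        k_idx = np.zeros(n_r, dtype=np.intp)
        r_rxn, r_sp, r_exp = [], [], []
        m_rows, m_rxn, m_kind, m_w, m_scale, m_kidx, m_kfix = [], [], [], [], [], [], []
        for j, rxn in enumerate(self.reactions):
            k_idx[j] = self.parameter_index[rxn.rate_param]
            for sp, n in rxn.reactants:
                i = self.species_index[sp]
                stoich[i, j] -= n
                r_rxn.append(j)
                r_sp.append(i)
                r_exp.append(n)
            for sp, n in rxn.products:
                stoich[self.species_index[sp], j] += n
            for mod in rxn.modifiers:
                row = np.zeros(n_s)
                for sp in mod.species:
                    row[self.species_index[sp]] = 1.0
                m_rows.append(row)
                m_rxn.append(j)
                m_kind.append(_KIND_CODE[mod.kind])
                m_w.append(
                    self.parameter_index[mod.weight_param]
                    if mod.weight_param is not None
                    else -1
                )
                m_scale.append(mod.scale)
                m_kidx.append(
                    self.parameter_index[mod.k_param] if mod.k_param is not None else -1
                )
                m_kfix.append(mod.k_value)
        dynamic = np.array([not s.constant for s in self.species])
        self._compiled = _Compiled(
            stoich=stoich,
            k_idx=k_idx,
            react_rxn=np.array(r_rxn, dtype=np.intp),
            react_sp=np.array(r_sp, dtype=np.intp),
            react_exp=np.array(r_exp, dtype=float),
            mod_matrix=np.array(m_rows) if m_rows else np.zeros((0, n_s)),
            mod_rxn=np.array(m_rxn, dtype=np.intp),
            mod_kind=np.array(m_kind, dtype=np.intp),
            mod_w_idx=np.array(m_w, dtype=np.intp),
            mod_scale=np.array(m_scale, dtype=float),
            mod_k_idx=np.array(m_kidx, dtype=np.intp),
            mod_k_fixed=np.array(m_kfix, dtype=float),
            dynamic_mask=dynamic,
        )
        return self._compiled

    def invalidate(self) -> None:
        """Drop the compiled representation after structural edits."""
        self._compiled = None

    def reaction_rates(self, state: np.ndarray, pvec: np.ndarray | None = None) -> np.ndarray:
        """Evaluate all reaction rates at the given state."""
        c = self.compile()
        p = self.parameter_vector() if pvec is None else pvec
        y = np.maximum(np.asarray(state, dtype=float), 0.0)
        rates = p[c.k_idx].copy()
        if c.react_rxn.size:
            contrib = y[c.react_sp] ** c.react_exp
            np.multiply.at(rates, c.react_rxn, contrib)
        if c.mod_rxn.size:
            sums = c.mod_matrix @ y
            w = np.where(c.mod_w_idx >= 0, p[np.maximum(c.mod_w_idx, 0)], 1.0)
            K = np.where(c.mod_k_idx >= 0, p[np.maximum(c.mod_k_idx, 0)], c.mod_k_fixed)
            x = sums / c.mod_scale
            factors = np.ones_like(sums)
            kind = c.mod_kind
            factors = np.where(kind == 0, sums, factors)  # mass
            factors = np.where(kind == 1, x, factors)  # scaled
            factors = np.where(kind == 2, 1.0 + w * x, factors)  # activate
            factors = np.where(kind == 3, 1.0 / (1.0 + w * x), factors)  # inhibit
            blocked = 1.0 - w * sums / (sums + K)
            factors = np.where(kind == 4, blocked, factors)  # block
            np.multiply.at(rates, c.mod_rxn, factors)
        return rates

    def derivatives(self, state: np.ndarray, t: float = 0.0, pvec: np.ndarray | None = None) -> np.ndarray:
        """Time derivative of the state vector (molecules/cell/min, nM/min).

        Clamped (constant) species have zero derivative; conservation-group
        totals have zero summed derivative by construction of the
        stoichiometry.
        """
        c = self.compile()
        rates = self.reaction_rates(state, pvec)
        if not np.all(np.isfinite(rates)):
            j = int(np.flatnonzero(~np.isfinite(rates))[0])
            raise RateEvaluationError(
                f"non-finite rate in reaction {self.reactions[j].name!r}"
            )
        dy = c.stoich @ rates
        dy[~c.dynamic_mask] = 0.0
        return dy

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<PathwayModel {self.name!r}: {self.n_species} species, "
            f"{self.n_parameters} parameters, {len(self.reactions)} reactions>"
        )
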