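"""Condition handling and stiff ODE simulation of the pathway model.

A :class:`Condition` describes one in-silico experiment: the HGF dose,
drug doses with optional pre-incubation windows, and the output grid.
Simulation proceeds piecewise:

1. relax the model for ``BASAL_RELAX_MIN`` minutes without stimulus so
   every condition starts from the same basal state;
2. apply drugs in order of decreasing pre-incubation time, integrating
   each drug-only segment;
3. add HGF at t = 0 and integrate to ``t_end``.

"Steady state" throughout the package means the value at t = 120 min;
the late timepoint stands in for a true fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import PathwayModel

__all__ = [
    "Condition",
    "Trajectory",
    "SimulationError",
    "simulate",
    "basal_state",
    "integrin_knockout_scenario",
    "percent_inhibition",
    "hgf_ng_ml_to_nM",
    "rk4_trajectory",
    "HGF_MW_KDA",
    "BASAL_RELAX_MIN",
]

# Molecular weight used to convert HGF doses quoted in ng/ml into nM.
# Mature two-chain HGF is ~84 kDa; configurable per call.
HGF_MW_KDA = 84.0
BASAL_RELAX_MIN = 20000.0
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-6


def hgf_ng_ml_to_nM(ng_ml: float, mw_kda: float = HGF_MW_KDA) -> float:
    return ng_ml / mw_kda


class SimulationError(RuntimeError):
    def __init__(self, message: str, condition: "Condition | None" = None, last_time: float | None = None):
        super().__init__(message)
        self.condition = condition
        self.last_time = last_time


@dataclass
class Condition:
    """An experimental scenario.

    ``hgf_dose`` is in ng/ml (default 40, the stimulation used throughout);
    ``drug_doses`` maps drug species names to doses in nM;
    ``pre_incubation`` maps drug names to minutes of exposure before HGF.
    """

    hgf_dose: float = 40.0
    drug_doses: dict[str, float] = field(default_factory=dict)
    pre_incubation: dict[str, float] = field(default_factory=dict)
    t_end: float = 120.0
    output_times: tuple[float, ...] | None = None
    hgf_mw_kda: float = HGF_MW_KDA

    def __post_init__(self) -> None:
        if self.hgf_dose < 0:
            raise ValueError("HGF dose must be non-negative")
        for drug, dose in self.drug_doses.items():
            if dose < 0:
                raise ValueError(f"negative dose for {drug}")
        if self.output_times is None:
            self.output_times = tuple(np.linspace(0.0, self.t_end, 25))
        else:
            self.output_times = tuple(float(t) for t in self.output_times)
        if self.t_end < max(self.output_times):
            raise ValueError("t_end must cover all output times")

    def with_doses(self, **doses: float) -> "Condition":
        new = dict(self.drug_doses)
        new.update(doses)
        return Condition(
            self.hgf_dose, new, dict(self.pre_incubation), self.t_end,
            self.output_times, self.hgf_mw_kda,
        )


@dataclass
class Trajectory:
    times: np.ndarray
    species_names: list[str]
    state: np.ndarray  # (n_times, n_species)
    readouts: dict[str, np.ndarray]

    def readout_at(self, name: str, t: float) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            return float(np.interp(t, self.times, self.readouts[name]))
        return float(self.readouts[name][i])

    def species_at(self, name: str, t: float) -> float:
        j = self.species_names.index(name)
        return float(np.interp(t, self.times, self.state[:, j]))

    def to_frame(self):
        import pandas as pd

        rows = []
        for rname, vals in self.readouts.items():
            for t, v in zip(self.times, vals):
                rows.append((float(t), rname, float(v)))
        return pd.DataFrame(rows, columns=["time_min", "readout", "value"])


def _integrate(model: PathwayModel, y0: np.ndarray, t0: float, t1: float,
               t_eval=None, rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
               condition: Condition | None = None) -> tuple[np.ndarray, np.ndarray]:
    pvec = model.parameter_vector()

    def rhs(t, y):
        return model.derivatives(y, t, pvec)

    sol = solve_ivp(
        rhs, (t0, t1), y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol,
        dense_output=False,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else t0
        raise SimulationError(
            f"solver failed: {sol.message}", condition=condition, last_time=last
        )
    return sol.t, sol.y.T


def basal_state(model: PathwayModel, rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL) -> np.ndarray:
    """Relaxed HGF-free, drug-free state used as the common starting point."""
    y0 = model.initial_state()
    hgf = model.species_index.get("HGF")
    if hgf is not None:
        y0[hgf] = 0.0
    _, ys = _integrate(model, y0, 0.0, BASAL_RELAX_MIN, t_eval=[BASAL_RELAX_MIN],
                       rtol=rtol, atol=atol)
    return ys[-1]


def _apply_rilotumumab_to_hgf(model: PathwayModel, condition: Condition, hgf_nM: float,
                              y0: np.ndarray) -> float:
    """Ligand depletion under excess antibody: HGF_free = HGF*Kd/(Kd+dose)."""
    dose = condition.drug_doses.get("Rilotumumab", 0.0)
    if dose <= 0:
        return hgf_nM
    kd = model.get_parameter("Kd_Rilo")
    if kd <= 0:
        raise ValueError("rilotumumab Kd must be positive")
    free = hgf_nM * kd / (kd + dose)
    if "Rilo_HGF" in model.species_index:
        y0[model.species_index["Rilo_HGF"]] = hgf_nM - free
    return free


def simulate(model: PathwayModel, condition: Condition, rtol=DEFAULT_RTOL,
             atol=DEFAULT_ATOL, y_basal: np.ndarray | None = None) -> Trajectory:
    """Simulate one condition from the shared basal state.

    ``y_basal`` may be supplied to reuse a precomputed basal state (it must
    come from the same model/parameter values).
    """
    y0 = basal_state(model, rtol=rtol, atol=atol) if y_basal is None else y_basal.copy()

    doses = dict(condition.drug_doses)
    preinc = {d: condition.pre_incubation.get(d, 0.0) for d in doses}
    hgf_nM = hgf_ng_ml_to_nM(condition.hgf_dose, condition.hgf_mw_kda)
    hgf_nM = _apply_rilotumumab_to_hgf(model, condition, hgf_nM, y0)

    # drug-only pre-incubation segments, longest first
    order = sorted(doses, key=lambda d: -preinc[d])
    t = -max([preinc[d] for d in doses], default=0.0)
    pending = list(order)
    while pending:
        d = pending[0]
        start = -preinc[d]
        if start > t:
            _, ys = _integrate(model, y0, t, start, t_eval=[start], rtol=rtol,
                               atol=atol, condition=condition)
            y0 = ys[-1]
            t = start
        if d != "Rilotumumab" and d in model.species_index:
            y0[model.species_index[d]] = doses[d]
        elif d != "Rilotumumab":
            raise ValueError(f"unknown drug species {d!r}")
        pending.pop(0)
        # drugs sharing this pre-incubation time are applied together
        while pending and abs(preinc[pending[0]] - preinc[d]) < 1e-12:
            d2 = pending.pop(0)
            if d2 != "Rilotumumab":
                y0[model.species_index[d2]] = doses[d2]
    if t < 0.0:
        _, ys = _integrate(model, y0, t, 0.0, t_eval=[0.0], rtol=rtol, atol=atol,
                           condition=condition)
        y0 = ys[-1]

    if "HGF" in model.species_index:
        y0[model.species_index["HGF"]] = hgf_nM

    t_eval = np.array(sorted(set(condition.output_times)))
    if t_eval[0] > 0.0:
        t_eval = np.concatenate([[0.0], t_eval])
    _, ys = _integrate(model, y0, 0.0, condition.t_end, t_eval=t_eval, rtol=rtol,
                       atol=atol, condition=condition)

    names, R = model.readout_matrix()
    readouts = {n: (ys @ R[i]) for i, n in enumerate(names)}
    return Trajectory(times=t_eval, species_names=[s.name for s in model.species],
                      state=ys, readouts=readouts)


# -- scenario operations ---------------------------------------------------

def integrin_knockout_scenario(model: PathwayModel, condition: Condition,
                               rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL) -> tuple[Trajectory, Trajectory]:
    """Baseline vs. Met signaling without any alpha5beta1 association.

    The knockout zeroes the Met–integrin association rate; constitutive
    trafficking of unphosphorylated Met is integrin-independent, so the
    total Met pool is preserved while the phospho-receptor loses the
    integrin-conferred trafficking protection.
    """
    base = simulate(model, condition, rtol=rtol, atol=atol)
    ko_model = model.copy()
    ko_model.set_parameters({"kon_Met_Itg": 0.0})
    ko = simulate(ko_model, condition, rtol=rtol, atol=atol)
    return base, ko


def percent_inhibition(model: PathwayModel, condition_drug: Condition,
                       condition_ref: Condition, readout: str, t: float,
                       rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
                       y_basal: np.ndarray | None = None) -> float:
    """100 * (1 - readout_drug(t) / readout_ref(t)); negative = increase."""
    ref = simulate(model, condition_ref, rtol=rtol, atol=atol, y_basal=y_basal)
    drug = simulate(model, condition_drug, rtol=rtol, atol=atol, y_basal=y_basal)
    denom = ref.readout_at(readout, t)
    if denom <= 0:
        raise ZeroDivisionError(
            f"reference readout {readout} non-positive at t={t}; inhibition undefined"
        )
    return 100.0 * (1.0 - drug.readout_at(readout, t) / denom)


# -- independent fixed-step oracle ----------------------------------------

def rk4_trajectory(model: PathwayModel, y0: np.ndarray, t_end: float, dt: float,
                   output_times: np.ndarray) -> np.ndarray:
    """Classic fixed-step RK4 integration, used as an integrator oracle."""
    pvec = model.parameter_vector()
    y = y0.astype(float).copy()
    t = 0.0
    out = np.empty((len(output_times), y.size))
    oi = 0
    times = np.asarray(output_times, dtype=float)
    n_steps = int(round(t_end / dt))
    for step in range(n_steps + 1):
        while oi < len(times) and times[oi] <= t + dt * 1e-6:
            out[oi] = y
            oi += 1
        if step == n_steps:
            break
        k1 = model.derivatives(y, t, pvec)
        k2 = model.derivatives(y + 0.5 * dt * k1, t + 0.5 * dt, pvec)
        k3 = model.derivatives(y + 0.5 * dt * k2, t + 0.5 * dt, pvec)
        k4 = model.derivatives(y + dt * k3, t + dt, pvec)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    while oi < len(times):
        out[oi] = y
        oi += 1
    return out
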