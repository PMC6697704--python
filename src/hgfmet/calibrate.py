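"""Calibration of free model parameters to normalized time-course data.

The experimental currency is immunoblot-style readouts normalized to a
control: each dataset carries means ± SD over time for one readout under
one condition.  Simulated readouts are normalized the same way — by
default to the maximum of the HGF-only control time course for the same
readout (switchable to per-condition maxima) — and compared by
root-mean-square error summed over datasets.

Fitting uses a derivative-free generalized pattern search in log10
parameter space: poll ± one mesh step per coordinate in a fixed order,
accept the first improvement, expand the mesh on success and contract it
on failure, and stop at a mesh tolerance or an evaluation budget.  The
algorithm is fully deterministic given its options.

The user-facing surface follows the Model/Results convention:
``CalibrationModel(model, datasets).fit()`` returns a
:class:`CalibrationResults` with estimates, the objective trace and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .network import PathwayModel
from .simulate import Condition, SimulationError, simulate

__all__ = [
    "ExperimentDataset",
    "FitResult",
    "objective",
    "pattern_search",
    "CalibrationModel",
    "CalibrationResults",
    "fit_inhibitor_strengths",
    "datasets_to_frame",
    "frame_to_datasets",
]

PENALTY_COST = 1e6
NORMALIZATIONS = ("control_max", "condition_max", "none")


@dataclass
class ExperimentDataset:
    """Normalized time-course observations for one readout and condition."""

    condition: Condition
    readout: str
    times: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    condition_id: str = "condition"
    normalization: str = "control_max"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.times) == len(self.means) == len(self.sds)):
            raise ValueError("times/means/sds must have equal length")
        if len(self.times) == 0:
            raise ValueError("dataset has no timepoints")
        if np.any(self.sds <= 0):
            raise ValueError("all SDs must be positive")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")


def datasets_to_frame(datasets: Sequence[ExperimentDataset]) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        for t, mu, sd in zip(ds.times, ds.means, ds.sds):
            rows.append((ds.condition_id, ds.readout, float(t), float(mu), float(sd)))
    return pd.DataFrame(rows, columns=["condition_id", "readout", "time_min", "mean", "sd"])


def frame_to_datasets(frame: pd.DataFrame, conditions: dict[str, Condition],
                      normalization: str = "control_max") -> list[ExperimentDataset]:
    out = []
    for (cid, readout), grp in frame.groupby(["condition_id", "readout"], sort=False):
        out.append(ExperimentDataset(
            conditions[cid], readout, grp["time_min"].to_numpy(),
            grp["mean"].to_numpy(), grp["sd"].to_numpy(),
            condition_id=cid, normalization=normalization,
        ))
    return out


def _condition_key(c: Condition) -> tuple:
    return (c.hgf_dose, tuple(sorted(c.drug_doses.items())),
            tuple(sorted(c.pre_incubation.items())), c.t_end)


def _simulate_datasets(model: PathwayModel, datasets: Sequence[ExperimentDataset],
                       rtol: float) -> dict[tuple, "object"]:
    """One simulation per distinct condition, on the union of its times."""
    from .simulate import basal_state

    y_basal = basal_state(model, rtol=rtol)
    cache: dict[tuple, object] = {}
    groups: dict[tuple, list[ExperimentDataset]] = {}
    for ds in datasets:
        groups.setdefault(_condition_key(ds.condition), []).append(ds)
    for key, members in groups.items():
        times = sorted({float(t) for ds in members for t in ds.times})
        base = members[0].condition
        cond = Condition(base.hgf_dose, dict(base.drug_doses),
                         dict(base.pre_incubation), max(base.t_end, times[-1]),
                         tuple(times), base.hgf_mw_kda)
        cache[key] = simulate(model, cond, rtol=rtol, y_basal=y_basal)
    return cache


def objective(model: PathwayModel, datasets: Sequence[ExperimentDataset],
              params: dict[str, float] | None = None, weighted: bool = False,
              rtol: float = 1e-6, control_condition: Condition | None = None) -> float:
    """Sum of per-dataset RMSEs between normalized simulation and data.

    A simulation failure yields the large finite :data:`PENALTY_COST`
    rather than an exception, so derivative-free search can continue.
    """
    if len(datasets) == 0:
        raise ValueError("no datasets")
    work = model.copy()
    if params:
        work.set_parameters(params)
    try:
        cache = _simulate_datasets(work, datasets, rtol)
        needs_control = any(ds.normalization == "control_max" for ds in datasets)
        control_traj = None
        if needs_control:
            ctrl = control_condition or Condition(
                hgf_dose=datasets[0].condition.hgf_dose,
                t_end=max(ds.condition.t_end for ds in datasets),
                output_times=tuple(sorted({float(t) for ds in datasets for t in ds.times})),
            )
            key = _condition_key(ctrl)
            control_traj = cache.get(key)
            if control_traj is None:
                from .simulate import basal_state
                control_traj = simulate(work, ctrl, rtol=rtol,
                                        y_basal=basal_state(work, rtol=rtol))
        total = 0.0
        for ds in datasets:
            traj = cache[_condition_key(ds.condition)]
            sim = np.array([traj.readout_at(ds.readout, t) for t in ds.times])
            if ds.normalization == "control_max":
                denom = float(np.max(control_traj.readouts[ds.readout]))
            elif ds.normalization == "condition_max":
                denom = float(np.max(sim))
            else:
                denom = 1.0
            if denom <= 0:
                return PENALTY_COST
            resid = sim / denom - ds.means
            if weighted:
                resid = resid / ds.sds
            total += float(np.sqrt(np.mean(resid ** 2)))
        if not np.isfinite(total):
            return PENALTY_COST
        return total
    except (SimulationError, FloatingPointError, OverflowError):
        return PENALTY_COST


@dataclass
class FitResult:
    parameters: dict[str, float]
    objective: float
    trace: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    converged: bool = False


def pattern_search(func: Callable[[np.ndarray], float], x0: np.ndarray,
                   lower: np.ndarray, upper: np.ndarray, step0: float = 0.25,
                   expand: float = 2.0, contract: float = 0.5,
                   mesh_tol: float = 1e-4, max_evals: int = 2000) -> tuple[np.ndarray, float, list[float], int]:
    """Deterministic bound-constrained generalized pattern search.

    Returns ``(x_best, f_best, trace, n_evals)``; the incumbent is never
    worse than ``x0``.
    """
    x = np.clip(np.asarray(x0, dtype=float), lower, upper)
    f = float(func(x))
    evals = 1
    trace = [f]
    mesh = float(step0)
    n = x.size
    while mesh > mesh_tol and evals < max_evals:
        improved = False
        for i in range(n):
            for sgn in (1.0, -1.0):
                cand = x.copy()
                cand[i] = np.clip(cand[i] + sgn * mesh, lower[i], upper[i])
                if cand[i] == x[i]:
                    continue
                fc = float(func(cand))
                evals += 1
                if fc < f:
                    x, f = cand, fc
                    trace.append(f)
                    improved = True
                    break
                if evals >= max_evals:
                    break
            if improved or evals >= max_evals:
                break
        mesh = mesh * expand if improved else mesh * contract
    return x, f, trace, evals


class CalibrationResults:
    """Estimates and diagnostics from a pattern-search calibration."""

    def __init__(self, model: PathwayModel, free_names: list[str],
                 fit: FitResult) -> None:
        self.model = model  # model carrying the fitted values
        self.free_names = free_names
        self.parameters = fit.parameters
        self.objective = fit.objective
        self.trace = fit.trace
        self.n_evaluations = fit.n_evaluations
        self.bounds = fit.bounds
        self.converged = fit.converged

    def params_frame(self) -> pd.DataFrame:
        rows = [
            (name, self.parameters[name], *self.bounds.get(name, (np.nan, np.nan)))
            for name in self.free_names
        ]
        return pd.DataFrame(rows, columns=["parameter", "estimate", "lower", "upper"])

    def summary(self) -> str:
        df = self.params_frame()
        lines = [
            "Pattern-search calibration results",
            "=" * 44,
            f"free parameters:      {len(self.free_names)}",
            f"objective (sum RMSE): {self.objective:.6g}",
            f"function evaluations: {self.n_evaluations}",
            f"converged (mesh tol): {self.converged}",
            "-" * 44,
            df.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<CalibrationResults: {len(self.free_names)} parameters, "
                f"objective={self.objective:.4g}>")


class CalibrationModel:
    """Pattern-search calibration of a pathway model to datasets.

    Parameters
    ----------
    model
        The pathway model; its ``free`` parameter flags define the default
        calibration set.
    datasets
        Normalized time-course observations.
    free
        Optional subset of parameter names to fit.
    weighted
        Divide residuals by the dataset SDs (default unweighted).
    """

    def __init__(self, model: PathwayModel, datasets: Sequence[ExperimentDataset],
                 free: Sequence[str] | None = None, weighted: bool = False,
                 rtol: float = 1e-6) -> None:
        self.model = model
        self.datasets = list(datasets)
        self.free_names = list(free) if free is not None else model.free_parameter_names
        for name in self.free_names:
            if name not in model.parameter_index:
                raise ValueError(f"unknown parameter {name!r}")
        self.weighted = weighted
        self.rtol = rtol

    def _bounds_log10(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name in self.free_names:
            p = self.model.parameters[self.model.parameter_index[name]]
            if p.bounds is not None and p.bounds[0] > 0:
                lo.append(np.log10(p.bounds[0]))
                hi.append(np.log10(p.bounds[1]))
            elif p.bounds is not None:
                # zero-allowed strength-like parameter: use a floor
                lo.append(-6.0)
                hi.append(np.log10(max(p.bounds[1], 1e-6)))
            else:
                lo.append(np.log10(p.value) - 2.0)
                hi.append(np.log10(p.value) + 2.0)
        return np.array(lo), np.array(hi)

    def _objective_log10(self) -> Callable[[np.ndarray], float]:
        names = self.free_names

        def fun(z: np.ndarray) -> float:
            params = {n: 10.0 ** v for n, v in zip(names, z)}
            return objective(self.model, self.datasets, params,
                             weighted=self.weighted, rtol=self.rtol)

        return fun

    def fit(self, x0: dict[str, float] | None = None, step0: float = 0.25,
            mesh_tol: float = 1e-3, max_evals: int = 400,
            expand: float = 2.0, contract: float = 0.5) -> CalibrationResults:
        lower, upper = self._bounds_log10()
        if x0 is None:
            z0 = np.array([
                np.log10(max(self.model.get_parameter(n), 1e-12))
                for n in self.free_names
            ])
        else:
            z0 = np.array([np.log10(max(x0[n], 1e-12)) for n in self.free_names])
        fun = self._objective_log10()
        z, fval, trace, evals = pattern_search(
            fun, z0, lower, upper, step0=step0, expand=expand,
            contract=contract, mesh_tol=mesh_tol, max_evals=max_evals,
        )
        params = {n: 10.0 ** v for n, v in zip(self.free_names, z)}
        fitted = self.model.copy()
        fitted.set_parameters(params)
        fit = FitResult(
            parameters=params, objective=fval, trace=trace,
            n_evaluations=evals,
            bounds={n: (10.0 ** lo, 10.0 ** hi)
                    for n, lo, hi in zip(self.free_names, lower, upper)},
            converged=evals < max_evals,
        )
        return CalibrationResults(fitted, self.free_names, fit)


def fit_inhibitor_strengths(model: PathwayModel,
                            mono_datasets: Sequence[ExperimentDataset],
                            strength_params: Sequence[str],
                            max_evals: int = 300) -> dict[str, float]:
    """Fit only node-inhibitor strengths with all other parameters frozen.

    Strengths live on [0, 1]; the search runs on that linear scale.
    """
    names = list(strength_params)
    lower = np.zeros(len(names))
    upper = np.ones(len(names))

    def fun(s: np.ndarray) -> float:
        params = dict(zip(names, s))
        return objective(model, mono_datasets, params)

    x0 = np.array([min(max(model.get_parameter(n), 0.0), 1.0) for n in names])
    s, _, _, _ = pattern_search(fun, x0, lower, upper, step0=0.2,
                                mesh_tol=1e-3, max_evals=max_evals)
    return dict(zip(names, s))
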