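"""Dose–response characterization and MuSyC two-drug synergy surfaces.

Single-drug curves are summarized by a four-parameter Hill fit

    E(d) = E0 + (Emax - E0) * d^h / (d^h + C^h),

with the IC50 given by C (the dose of half-maximal effect change).

Two-drug response grids are fitted with the MuSyC two-dimensional Hill
surface (single potency-interaction factor, unit cooperativity):

    E(d1, d2) = (E0 + E1*a1 + E2*a2 + E3*α*a1*a2)
                / (1 + a1 + a2 + α*a1*a2),     a_i = (d_i / C_i)^h_i

where E1, E2 are the single-drug maximal-effect plateaus, E3 the
combination plateau, and α (reported as log10 α₂) rescales the potency of
the second drug in the presence of the first: log α₂ > 0 means the
combination reaches its effect at lower doses (synergistic potency),
log α₂ < 0 antagonistic potency.  Efficacy synergy is measured by

    β = (min(E1, E2) - E3) / (E0 - min(E1, E2)),

the gain of the combination plateau beyond the stronger single drug,
normalized to that drug's effect window; ``beta_obs`` evaluates the same
expression on the observed corner responses of the tested grid (maximum
tested doses) rather than fitted asymptotes.  Effects are normalized
readouts (fraction of the zero-drug control), so E0 ≈ 1 and lower E means
stronger inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .network import PathwayModel
from .perturb import DRUGS
from .simulate import Condition, basal_state, simulate

__all__ = [
    "DoseResponse",
    "HillFit",
    "fit_ic50",
    "dose_response",
    "MusycModel",
    "MusycResults",
    "fit_musyc_surface",
    "beta_obs",
    "musyc_effect",
    "response_grid",
    "isobologram",
    "default_grid",
    "FitQualityError",
]


class FitQualityError(RuntimeError):
    """Dose–response data unsuitable for a Hill fit (flat/non-spanning)."""


@dataclass
class DoseResponse:
    drug: str
    doses: np.ndarray  # nM, strictly increasing, without the zero anchor
    effects: np.ndarray  # readout / zero-dose readout
    readout: str
    time: float
    zero_dose_value: float  # raw readout at dose 0

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.effects = np.asarray(self.effects, dtype=float)
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")


@dataclass
class HillFit:
    E0: float
    Emax: float
    h: float
    C: float
    residual: float

    @property
    def ic50(self) -> float:
        return self.C

    def __call__(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return self.E0 + (self.Emax - self.E0) * d ** self.h / (d ** self.h + self.C ** self.h)


def hill_curve(d: np.ndarray, E0: float, Emax: float, h: float, C: float) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    return E0 + (Emax - E0) * d ** h / (d ** h + C ** h)


def fit_ic50(dr: DoseResponse, span_fraction: float = 0.5) -> HillFit:
    """Least-squares four-parameter Hill fit; C is the IC50.

    Requires the observed effect to span at least ``span_fraction`` of the
    fitted dynamic range so that the half-maximal dose is interpolated,
    not extrapolated.
    """
    d = np.concatenate([[0.0], dr.doses])
    e = np.concatenate([[1.0], dr.effects])
    rng = float(e.max() - e.min())
    if rng < 0.05:
        raise FitQualityError(
            f"{dr.drug}/{dr.readout}: flat dose-response (range {rng:.3g})"
        )
    e0 = float(e[0])
    emax0 = float(e[-1])
    c0 = float(np.sqrt(dr.doses[0] * dr.doses[-1]))

    def resid(p):
        E0, Emax, logh, logC = p
        return hill_curve(d, E0, Emax, np.exp(logh), np.exp(logC)) - e

    lo = [e.min() - 0.5 * rng, e.min() - 0.5 * rng, np.log(0.2), np.log(dr.doses[0] / 30.0)]
    hi = [e.max() + 0.5 * rng, e.max() + 0.5 * rng, np.log(6.0), np.log(dr.doses[-1] * 30.0)]
    sol = least_squares(resid, [e0, emax0, 0.0, np.log(c0)], bounds=(lo, hi))
    E0, Emax, h, C = sol.x[0], sol.x[1], float(np.exp(sol.x[2])), float(np.exp(sol.x[3]))
    fit = HillFit(float(E0), float(Emax), h, C, float(np.sqrt(np.mean(sol.fun ** 2))))
    span = abs(e0 - emax0) / max(abs(E0 - Emax), 1e-12)
    if span < span_fraction:
        raise FitQualityError(
            f"{dr.drug}/{dr.readout}: observed span covers only {span:.0%} of "
            "the fitted dynamic range"
        )
    return fit


def dose_response(model: PathwayModel, drug: str, grid: Sequence[float],
                  readout: str, t: float = 120.0, hgf_dose: float = 40.0,
                  rtol: float = 1e-6, y_basal: np.ndarray | None = None) -> DoseResponse:
    """Simulated effect (fraction of zero-dose control) over a dose grid,
    under HGF stimulation."""
    doses = np.asarray(sorted(set(float(x) for x in grid if x > 0)))
    spec = DRUGS.get(drug)
    times = (t,) if t > 0 else (0.0, t)
    cond0 = Condition(hgf_dose=hgf_dose, output_times=times, t_end=t)
    yb = basal_state(model, rtol=rtol) if y_basal is None else y_basal
    ref = simulate(model, cond0, rtol=rtol, y_basal=yb).readout_at(readout, t)
    if ref <= 0:
        raise ZeroDivisionError(f"zero-dose {readout} is non-positive")
    effects = []
    for dose in doses:
        cond = cond0.with_doses(**{drug: float(dose)})
        traj = simulate(model, cond, rtol=rtol, y_basal=yb)
        effects.append(traj.readout_at(readout, t) / ref)
    name = spec.name if spec else drug
    return DoseResponse(name, doses, np.array(effects), readout, t, float(ref))


# ------------------------------------------------------------------ MuSyC

def musyc_effect(d1, d2, E0, E1, E2, E3, h1, h2, C1, C2, alpha):
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    a1 = (d1 / C1) ** h1
    a2 = (d2 / C2) ** h2
    num = E0 + E1 * a1 + E2 * a2 + E3 * alpha * a1 * a2
    den = 1.0 + a1 + a2 + alpha * a1 * a2
    return num / den


@dataclass
class MusycResults:
    """Fitted MuSyC surface with potency/efficacy synergy metrics."""

    E0: float
    E1: float
    E2: float
    E3: float
    h1: float
    h2: float
    C1: float
    C2: float
    alpha2: float
    residual: float
    grid: pd.DataFrame  # the data the surface was fitted to

    @property
    def log_alpha2(self) -> float:
        return float(np.log10(self.alpha2))

    @property
    def beta(self) -> float:
        """Efficacy synergy from fitted plateaus."""
        e_single = min(self.E1, self.E2)
        return float((e_single - self.E3) / (self.E0 - e_single))

    @property
    def beta_obs(self) -> float:
        """Efficacy synergy from the observed corner responses."""
        g = self.grid
        d1m, d2m = g["d1"].max(), g["d2"].max()

        def at(d1, d2):
            row = g[(g["d1"] == d1) & (g["d2"] == d2)]
            return float(row["effect"].iloc[0])

        e0, e1 = at(0.0, 0.0), at(d1m, 0.0)
        e2, e3 = at(0.0, d2m), at(d1m, d2m)
        e_single = min(e1, e2)
        return float((e_single - e3) / (e0 - e_single))

    def effect(self, d1, d2):
        return musyc_effect(d1, d2, self.E0, self.E1, self.E2, self.E3,
                            self.h1, self.h2, self.C1, self.C2, self.alpha2)

    def summary(self) -> str:
        return "\n".join([
            "MuSyC surface fit",
            "=" * 40,
            f"E0={self.E0:.4f}  E1={self.E1:.4f}  E2={self.E2:.4f}  E3={self.E3:.4f}",
            f"h1={self.h1:.3f}  h2={self.h2:.3f}  C1={self.C1:.4g} nM  C2={self.C2:.4g} nM",
            f"log10(alpha2) = {self.log_alpha2:+.3f}   (potency synergy if > 0)",
            f"beta (fitted) = {self.beta:+.4f}   beta_obs = {self.beta_obs:+.4f}",
            f"RMS residual  = {self.residual:.4g}",
        ])


class MusycModel:
    """MuSyC surface fitted to a two-drug response grid.

    The grid DataFrame needs columns ``d1``, ``d2``, ``effect`` and must
    include both single-drug axes and the (0, 0) corner.
    """

    def __init__(self, grid: pd.DataFrame) -> None:
        required = {"d1", "d2", "effect"}
        if not required.issubset(grid.columns):
            raise ValueError(f"grid must have columns {sorted(required)}")
        if not ((grid["d1"] == 0) & (grid["d2"] == 0)).any():
            raise ValueError("grid must include the zero-zero anchor")
        if grid[(grid["d2"] == 0) & (grid["d1"] > 0)].empty or \
           grid[(grid["d1"] == 0) & (grid["d2"] > 0)].empty:
            raise ValueError("grid must include both single-drug axes")
        if grid[(grid["d1"] > 0) & (grid["d2"] > 0)].empty:
            raise ValueError("grid has no combination points (degenerate)")
        self.grid = grid.reset_index(drop=True)

    def _axis_fit(self, axis: str) -> HillFit:
        other = "d2" if axis == "d1" else "d1"
        sub = self.grid[self.grid[other] == 0].sort_values(axis)
        sub = sub[sub[axis] >= 0]
        doses = sub[axis].to_numpy()
        effects = sub["effect"].to_numpy()
        dr = DoseResponse("axis", doses[doses > 0], effects[doses > 0] / effects[0],
                          "effect", 0.0, float(effects[0]))
        try:
            return fit_ic50(dr, span_fraction=0.0)
        except FitQualityError:
            return HillFit(1.0, float(effects[-1] / effects[0]), 1.0,
                           float(np.median(doses[doses > 0])), np.inf)

    def fit(self) -> MusycResults:
        g = self.grid
        d1 = g["d1"].to_numpy()
        d2 = g["d2"].to_numpy()
        e = g["effect"].to_numpy()
        f1 = self._axis_fit("d1")
        f2 = self._axis_fit("d2")
        e00 = float(g[(g["d1"] == 0) & (g["d2"] == 0)]["effect"].iloc[0])
        rng = float(e.max() - e.min())
        p0 = np.array([
            e00, f1.Emax * e00, f2.Emax * e00, float(e.min()),
            np.log(np.clip(f1.h, 0.25, 5.0)), np.log(np.clip(f2.h, 0.25, 5.0)),
            np.log(f1.C), np.log(f2.C), 0.0,
        ])
        pos1 = d1[d1 > 0]
        pos2 = d2[d2 > 0]
        lo = [e.min() - rng, e.min() - rng, e.min() - rng, e.min() - rng,
              np.log(0.2), np.log(0.2),
              np.log(pos1.min() / 100.0), np.log(pos2.min() / 100.0),
              np.log(10.0 ** -3)]
        hi = [e.max() + rng, e.max() + rng, e.max() + rng, e.max() + rng,
              np.log(6.0), np.log(6.0),
              np.log(pos1.max() * 100.0), np.log(pos2.max() * 100.0),
              np.log(10.0 ** 3)]
        p0 = np.clip(p0, lo, hi)

        def resid(p):
            E0, E1, E2, E3 = p[0], p[1], p[2], p[3]
            h1, h2 = np.exp(p[4]), np.exp(p[5])
            C1, C2 = np.exp(p[6]), np.exp(p[7])
            alpha = np.exp(p[8])
            return musyc_effect(d1, d2, E0, E1, E2, E3, h1, h2, C1, C2, alpha) - e

        sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        p = sol.x
        return MusycResults(
            E0=float(p[0]), E1=float(p[1]), E2=float(p[2]), E3=float(p[3]),
            h1=float(np.exp(p[4])), h2=float(np.exp(p[5])),
            C1=float(np.exp(p[6])), C2=float(np.exp(p[7])),
            alpha2=float(np.exp(p[8])),
            residual=float(np.sqrt(np.mean(sol.fun ** 2))),
            grid=self.grid,
        )


def fit_musyc_surface(grid: pd.DataFrame) -> MusycResults:
    """Convenience wrapper: fit the MuSyC surface to a response grid."""
    return MusycModel(grid).fit()


def beta_obs(surface: MusycResults) -> float:
    """Observed efficacy synergy of a fitted surface."""
    return surface.beta_obs


def default_grid(drug: str, n: int = 8) -> np.ndarray:
    """Log-spaced dose grid over the drug's therapeutic range (no zero)."""
    lo, hi = DRUGS[drug].dose_range
    return np.geomspace(lo, hi, n)


def response_grid(model: PathwayModel, drug1: str, drug2: str, readout: str,
                  t: float = 120.0, doses1: Sequence[float] | None = None,
                  doses2: Sequence[float] | None = None, hgf_dose: float = 40.0,
                  rtol: float = 1e-6) -> pd.DataFrame:
    """Simulate the (doses1 + 0) × (doses2 + 0) response grid.

    Effects are normalized to the zero-zero (HGF-only) corner.
    """
    doses1 = default_grid(drug1) if doses1 is None else np.asarray(doses1, float)
    doses2 = default_grid(drug2) if doses2 is None else np.asarray(doses2, float)
    yb = basal_state(model, rtol=rtol)
    cond0 = Condition(hgf_dose=hgf_dose, output_times=(t,), t_end=t)
    ref = simulate(model, cond0, rtol=rtol, y_basal=yb).readout_at(readout, t)
    rows = []
    for a in np.concatenate([[0.0], doses1]):
        for b in np.concatenate([[0.0], doses2]):
            cond = cond0.with_doses(**{drug1: float(a), drug2: float(b)})
            traj = simulate(model, cond, rtol=rtol, y_basal=yb)
            rows.append((float(a), float(b), traj.readout_at(readout, t) / ref))
    return pd.DataFrame(rows, columns=["d1", "d2", "effect"])


def response_grids(model: PathwayModel, drug1: str, drug2: str,
                   readouts: Sequence[str], t: float = 120.0,
                   doses1: Sequence[float] | None = None,
                   doses2: Sequence[float] | None = None,
                   hgf_dose: float = 40.0, rtol: float = 1e-6
                   ) -> dict[str, pd.DataFrame]:
    """Response grids for several readouts sharing one set of simulations."""
    doses1 = default_grid(drug1) if doses1 is None else np.asarray(doses1, float)
    doses2 = default_grid(drug2) if doses2 is None else np.asarray(doses2, float)
    yb = basal_state(model, rtol=rtol)
    cond0 = Condition(hgf_dose=hgf_dose, output_times=(t,), t_end=t)
    ref = simulate(model, cond0, rtol=rtol, y_basal=yb)
    rows: dict[str, list] = {r: [] for r in readouts}
    for a in np.concatenate([[0.0], doses1]):
        for b in np.concatenate([[0.0], doses2]):
            cond = cond0.with_doses(**{drug1: float(a), drug2: float(b)})
            traj = simulate(model, cond, rtol=rtol, y_basal=yb)
            for r in readouts:
                rows[r].append((float(a), float(b),
                                traj.readout_at(r, t) / ref.readout_at(r, t)))
    return {r: pd.DataFrame(v, columns=["d1", "d2", "effect"])
            for r, v in rows.items()}


def isobologram(surface_fn: Callable[[float, float], float] | MusycResults,
                level: float, d1_max: float, d2_max: float,
                n: int = 41) -> pd.DataFrame:
    """Dose-pair contour achieving a fractional inhibition ``level``.

    ``level`` is relative inhibition (0–1) of the zero-dose effect; the
    contour starts and ends at the single-drug doses achieving it.
    """
    fn = surface_fn.effect if isinstance(surface_fn, MusycResults) else surface_fn
    e0 = float(fn(0.0, 0.0))
    target = e0 * (1.0 - level)

    def solve_axis(which: int, dmax: float) -> float:
        g = (lambda d: float(fn(d, 0.0)) - target) if which == 1 else \
            (lambda d: float(fn(0.0, d)) - target)
        if g(dmax) > 0:
            raise ValueError(
                f"inhibition level {level:.2f} not reachable on drug-{which} axis"
            )
        return brentq(g, 0.0, dmax, xtol=1e-12, rtol=1e-10)

    d1_star = solve_axis(1, d1_max)
    d2_star = solve_axis(2, d2_max)
    rows = [(0.0, d2_star)]
    for d1 in np.linspace(0.0, d1_star, n)[1:-1]:
        g = lambda d: float(fn(d1, d)) - target
        if g(0.0) <= 0:  # already past the level with drug 1 alone
            rows.append((float(d1), 0.0))
            continue
        rows.append((float(d1), float(brentq(g, 0.0, d2_max, xtol=1e-12, rtol=1e-10))))
    rows.append((d1_star, 0.0))
    return pd.DataFrame(rows, columns=["d1", "d2"])
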