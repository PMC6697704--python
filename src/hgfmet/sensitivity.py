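"""Global sensitivity analysis: Latin hypercube sampling + PRCC.

All rate parameters and protein abundances are varied simultaneously and
uniformly within a ± fraction (default 50%) of their nominal values using
a seeded Latin hypercube.  Partial rank correlation coefficients are
computed per input against each model output: rank-transform everything,
regress the input and the output on all remaining inputs, and correlate
the two residual vectors.  Significance uses the t statistic
``t = r * sqrt((n - 2 - k) / (1 - r^2))`` with ``k`` conditioning
variables; entries with p above the cutoff are zeroed in the reported
(heatmap-style) tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .network import PathwayModel
from .simulate import Condition, basal_state, simulate

__all__ = ["lhs_sample", "prcc", "SensitivityResult", "sensitivity_pipeline"]


def lhs_sample(nominal: np.ndarray, n: int, fraction: float = 0.5,
               seed: int = 0) -> np.ndarray:
    """Latin hypercube sample of ``n`` points within ± ``fraction`` of the
    nominal vector (linear scale); one draw per equal-probability stratum
    and per column."""
    nominal = np.asarray(nominal, dtype=float)
    sampler = qmc.LatinHypercube(d=nominal.size, seed=seed)
    u = sampler.random(n)
    lo = nominal * (1.0 - fraction)
    hi = nominal * (1.0 + fraction)
    return lo + u * (hi - lo)


def _rank(a: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, a)


def prcc(samples: np.ndarray, output: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partial rank correlation of each column of ``samples`` with
    ``output``.

    Returns ``(coefficients, p_values)``.  Raises on constant or
    perfectly collinear columns, which make the partial regression
    rank-deficient.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(output, dtype=float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ValueError("samples and output lengths differ")
    const = np.ptp(X, axis=0) == 0
    if np.any(const):
        raise ValueError(f"constant sample columns: {np.flatnonzero(const).tolist()}")
    Xr = _rank(X)
    yr = stats.rankdata(y)
    k = p - 1  # conditioning variables per partial correlation
    coeffs = np.empty(p)
    pvals = np.empty(p)
    for j in range(p):
        others = np.delete(Xr, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        beta_x, _, rank_x, _ = np.linalg.lstsq(A, Xr[:, j], rcond=None)
        beta_y, _, _, _ = np.linalg.lstsq(A, yr, rcond=None)
        if rank_x < A.shape[1]:
            raise ValueError(f"rank-deficient regression for column {j}")
        rx = Xr[:, j] - A @ beta_x
        ry = yr - A @ beta_y
        denom = np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2))
        r = 0.0 if denom == 0 else float(np.dot(rx, ry) / denom)
        r = float(np.clip(r, -1.0, 1.0))
        df = n - 2 - k
        if df <= 0:
            raise ValueError("not enough samples for the partial correlation")
        if abs(r) >= 1.0:
            pv = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r ** 2))
            pv = 2.0 * stats.t.sf(abs(t), df)
        coeffs[j] = r
        pvals[j] = pv
    return coeffs, pvals


@dataclass
class SensitivityResult:
    samples: pd.DataFrame  # n × p input matrix
    outputs: pd.DataFrame  # n × m output matrix
    prcc: pd.DataFrame  # p × m coefficients
    pvalues: pd.DataFrame  # p × m
    n_failed: int = 0
    alpha: float = 0.01

    def significant(self) -> pd.DataFrame:
        """PRCC table with insignificant entries replaced by zero."""
        return self.prcc.where(self.pvalues < self.alpha, 0.0)


#: Outputs reported by the default pipeline (readout @ minutes).
PIPELINE_OUTPUTS = (
    ("pAkt", 15.0), ("pAkt", 120.0),
    ("pERK", 15.0), ("pERK", 120.0),
    ("pMet_surface", 15.0), ("pMet_surface", 120.0),
    ("pMet_internal", 15.0), ("pMet_internal", 120.0),
)


def sensitivity_pipeline(model: PathwayModel, n: int = 500, fraction: float = 0.5,
                         seed: int = 0, parameters: Sequence[str] | None = None,
                         abundances: Sequence[str] | None = None,
                         outputs: Sequence[tuple[str, float]] = PIPELINE_OUTPUTS,
                         alpha: float = 0.01, rtol: float = 1e-6) -> SensitivityResult:
    """Sample, simulate, and compute significance-filtered PRCC tables.

    Inputs are the model's free rate parameters plus protein abundances
    (initial amounts of non-zero, non-constant species).  Failed
    simulations are dropped with their count reported.
    """
    if parameters is None:
        parameters = model.free_parameter_names
    if abundances is None:
        abundances = [s.name for s in model.species
                      if not s.constant and s.initial_amount > 0]
    names = [f"k:{p}" for p in parameters] + [f"ab:{a}" for a in abundances]
    nominal = np.array(
        [model.get_parameter(p) for p in parameters]
        + [model.species[model.species_index[a]].initial_amount for a in abundances]
    )
    X = lhs_sample(nominal, n, fraction=fraction, seed=seed)

    out_names = [f"{r}@{t:g}" for r, t in outputs]
    times = tuple(sorted({t for _, t in outputs}))
    cond = Condition(hgf_dose=40.0, output_times=times, t_end=max(times))
    rows, ok = [], []
    np_params = len(parameters)
    for i in range(n):
        work = model.copy()
        work.set_parameters(dict(zip(parameters, X[i, :np_params])))
        work.set_initial(dict(zip(abundances, X[i, np_params:])))
        try:
            traj = simulate(work, cond, rtol=rtol,
                            y_basal=basal_state(work, rtol=rtol))
            rows.append([traj.readout_at(r, t) for r, t in outputs])
            ok.append(i)
        except Exception:
            continue
    n_failed = n - len(ok)
    Xok = X[ok]
    Y = np.asarray(rows)
    coeffs = np.empty((len(names), len(out_names)))
    pvals = np.empty_like(coeffs)
    for m_i in range(len(out_names)):
        coeffs[:, m_i], pvals[:, m_i] = prcc(Xok, Y[:, m_i])
    return SensitivityResult(
        samples=pd.DataFrame(Xok, columns=names),
        outputs=pd.DataFrame(Y, columns=out_names),
        prcc=pd.DataFrame(coeffs, index=names, columns=out_names),
        pvalues=pd.DataFrame(pvals, index=names, columns=out_names),
        n_failed=n_failed,
        alpha=alpha,
    )
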