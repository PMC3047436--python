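"""Post-fit analyses: one-at-a-time parametric sensitivity, eigenvalue
time-scale classification, and the DNA-to-protein rate-unit conversion.

Sensitivity follows the fold-change-of-maximum convention: each rate constant
is scaled over a ratio grid (two-fold up and down by default), the treatment
condition is re-simulated, and the maximum concentration of every metabolite
is compared with its unperturbed maximum; the slope at ratio 1 (central
difference with a +-10% step) is the scalar sensitivity.

Time scales come from the eigen-decomposition of the state Jacobian at the
control steady state.  A metabolite "contributes" to an eigenvector when its
normalised component magnitude is at least 0.3; each metabolite is assigned
the slowest (smallest |Re lambda|) eigenvalue among those it contributes to
— the slow manifold governs its approach to steady state — and bucketed as
fast (< 3 hr), medium (3-30 hr) or slow (> 30 hr) by characteristic time
1/|Re lambda|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .network import RateParams, ReactionNetwork
from .simulate import jacobian, simulate, steady_state
from .timecourse import ConditionDataset

__all__ = [
    "SensitivityResult",
    "TimescaleResult",
    "sensitivity_scan",
    "timescale_classification",
    "convert_rate_units",
    "invert_rate_units",
    "DEFAULT_RATIOS",
]

DEFAULT_RATIOS = (0.5, 0.667, 1.0, 1.5, 2.0)
# pmol/hr/ug-DNA -> pmol/min/mg-protein: ~3 ug DNA and ~0.25 mg protein per 1e6 cells
_UG_DNA_PER_1E6_CELLS = 3.0
_MG_PROTEIN_PER_1E6_CELLS = 0.25
_MIN_PER_HR = 60.0


@dataclass
class SensitivityResult:
    """Fold-change of trajectory maxima under scaling of one rate constant."""

    param: str
    ratios: np.ndarray
    fold_change: pd.DataFrame   # index ratios, columns metabolites
    slope: pd.Series            # d(fold-change)/d(ratio) at ratio 1

    def to_long_frame(self) -> pd.DataFrame:
        long = self.fold_change.stack().rename("fold_change").reset_index()
        long.columns = ["ratio", "metabolite", "fold_change"]
        long.insert(0, "param", self.param)
        long["slope"] = long["metabolite"].map(self.slope)
        return long


def _max_abundances(network, params, dataset, condition, x0, t_dense, **sim_kw):
    traj = simulate(network, params, x0, dataset, condition, t_grid=t_dense, **sim_kw)
    return traj.states.max(axis=0)


def sensitivity_scan(network: ReactionNetwork, params: RateParams, dataset: ConditionDataset,
                     param_name: str, ratios=DEFAULT_RATIOS, *, condition: str = "treatment",
                     x0=None, slope_step: float = 0.1, n_dense: int = 241,
                     rtol: float = 1e-8, atol: float = 1e-11) -> SensitivityResult:
    """One-at-a-time sensitivity of every metabolite's maximum to one constant."""
    if param_name not in network.param_names:
        raise KeyError(f"unknown rate constant {param_name!r}")
    base = params[param_name]
    if x0 is None:
        x0 = dataset.state_matrix(condition)[0]
    grid = dataset.grid(condition)
    t_dense = np.linspace(grid[0], grid[-1], n_dense)
    sim_kw = dict(rtol=rtol, atol=atol, method="LSODA")
    ref_max = np.maximum(_max_abundances(network, params, dataset, condition, x0, t_dense, **sim_kw), 1e-300)

    ratios = np.asarray(ratios, dtype=float)
    species = list(network.catalog.dynamic_species)
    rows = {}
    failures = {}
    for r in ratios:
        if r == 1.0:
            rows[r] = np.ones(len(species))
            continue
        try:
            m = _max_abundances(network, params.replace(**{param_name: r * base}),
                                dataset, condition, x0, t_dense, **sim_kw)
            rows[r] = m / ref_max
        except Exception as exc:  # noqa: BLE001 - reported per ratio
            failures[r] = str(exc)
    if failures:
        raise RuntimeError(f"simulation failed at ratios {failures}")
    fold = pd.DataFrame([rows[r] for r in ratios], index=pd.Index(ratios, name="ratio"),
                        columns=species)

    slopes = {}
    for sign_r in (1.0 - slope_step, 1.0 + slope_step):
        m = _max_abundances(network, params.replace(**{param_name: sign_r * base}),
                            dataset, condition, x0, t_dense, **sim_kw)
        slopes[sign_r] = m / ref_max
    slope = pd.Series((slopes[1.0 + slope_step] - slopes[1.0 - slope_step]) / (2 * slope_step),
                      index=species, name="slope")
    return SensitivityResult(param_name, ratios, fold, slope)


@dataclass
class TimescaleResult:
    """Eigen-structure of the steady-state Jacobian and metabolite categories."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    assignment: pd.DataFrame   # metabolite, eigenvalue, tau_hr, category
    steady_state: np.ndarray
    converged: bool

    def category(self, metabolite: str) -> str:
        return str(self.assignment.set_index("metabolite").loc[metabolite, "category"])


def timescale_classification(network: ReactionNetwork, params: RateParams,
                             dataset: ConditionDataset, *, thresholds=(3.0, 30.0),
                             contribution: float = 0.3) -> TimescaleResult:
    """Classify each metabolite as fast/medium/slow from the steady-state Jacobian."""
    ss = steady_state(network, params, dataset)
    if not ss.converged:
        raise RuntimeError(
            f"steady state did not converge (||rhs||_inf = {ss.residual:.3g}); "
            "cannot classify time scales"
        )
    inputs0 = dataset.inputs_at(float(dataset.grid("control")[0]), "control")
    J = jacobian(network, params, ss.state, inputs0)
    lam, V = linalg.eig(J)
    order = np.argsort(np.abs(lam.real))  # slowest first
    lam, V = lam[order], V[:, order]
    if np.any(np.abs(lam.real) < 1e-12):
        raise RuntimeError("Jacobian has a (numerically) zero eigenvalue; time scales undefined")

    fast_hr, slow_hr = thresholds
    species = network.catalog.dynamic_species
    records = []
    for i, sp in enumerate(species):
        contrib = np.abs(V[i, :]) / np.max(np.abs(V), axis=0)
        candidates = np.flatnonzero(contrib >= contribution)
        if candidates.size == 0:  # degenerate; fall back to the largest component
            candidates = np.array([int(np.argmax(contrib))])
        j = candidates[0]  # eigenvalues are sorted slowest-first
        tau = 1.0 / abs(lam[j].real)
        category = "fast" if tau < fast_hr else ("medium" if tau <= slow_hr else "slow")
        records.append({"metabolite": sp, "eigenvalue": lam[j].real, "tau_hr": tau,
                        "category": category})
    return TimescaleResult(lam, V, pd.DataFrame(records), ss.state, ss.converged)


def convert_rate_units(x: float) -> float:
    """Convert a flux from pmol/hr/ug-DNA to pmol/min/mg-protein."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("rates must be nonnegative")
    return x * _UG_DNA_PER_1E6_CELLS / _MG_PROTEIN_PER_1E6_CELLS / _MIN_PER_HR


def invert_rate_units(x: float) -> float:
    """Inverse of :func:`convert_rate_units`."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("rates must be nonnegative")
    return x * _MIN_PER_HR * _MG_PROTEIN_PER_1E6_CELLS / _UG_DNA_PER_1E6_CELLS
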