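"""Synthetic dual-condition datasets with the structure the estimator assumes.

The generator emulates the experimental design: 8 samples over 24 hr under
control and endotoxin-treatment conditions, 3 biological x 3 technical
replicates, and ~20-30% fractional SEM.  Treatment input shapes encode the
qualitative behaviour of the measured drivers: sphinganine doubles by 4 hr
and returns to baseline by 24 hr, palmitoyl-CoA rises monotonically, and the
gene folds start at 1 and diverge after 2-4 hr with pairwise non-proportional
shapes (an identifiability guard for enzymes sharing a substrate).  All
profiles are piecewise-linear on the sampling grid, so the interpolants used
during fitting reproduce the generating inputs exactly.

Replicate noise is multiplicative lognormal (concentrations are positive and
observed dispersion is a roughly constant coefficient of variation); the
``noise_frac_sem`` parameter targets the fractional SEM of the replicate
mean, i.e. per-replicate CV = noise_frac_sem * sqrt(n_replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import RateParams, ReactionNetwork
from .timecourse import DEFAULT_GRID, ConditionDataset, ReplicateTable, TimeCourse
from .simulate import simulate

__all__ = ["ProfileSpec", "SyntheticTruth", "default_input_profiles", "generate_dataset",
           "control_steady_state"]


@dataclass(frozen=True)
class ProfileSpec:
    """Piecewise-linear input profile on the sampling grid."""

    name: str
    condition: str
    shape: str  # constant | rise-return | monotone-saturating | late-upregulation | transient
    values: tuple[float, ...]
    times: tuple[float, ...] = tuple(DEFAULT_GRID)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.times):
            raise ValueError(f"{self.name}: profile values must match the time grid")
        if any(v <= 0 for v in self.values):
            raise ValueError(f"{self.name}: profiles must be strictly positive")

    def as_timecourse(self) -> TimeCourse:
        return TimeCourse(self.name, self.condition, np.array(self.times), np.array(self.values))


_CONTROL_LIPIDS = {"DHSph": 5.0, "CoA16": 1.0, "C16DG": 0.1, "C16GPCho": 5.0}

# treatment drivers: sphinganine doubles at 4 hr and is back to baseline at 24 hr;
# palmitoyl-CoA increases monotonically over 0-24 hr
_TREATMENT_LIPIDS = {
    "DHSph": ("rise-return", (5.0, 5.5, 6.2, 7.5, 10.0, 9.0, 7.5, 5.0)),
    "CoA16": ("monotone-saturating", (1.0, 1.05, 1.1, 1.2, 1.4, 1.6, 1.8, 2.0)),
    "C16DG": ("transient", (0.1, 0.1, 0.105, 0.11, 0.12, 0.13, 0.125, 0.12)),
    "C16GPCho": ("transient", (5.0, 5.0, 5.1, 5.3, 5.6, 6.0, 6.2, 6.0)),
}

# treatment gene folds: start at 1, diverge after ~2-4 hr, pairwise non-proportional
_TREATMENT_GENES = {
    "CerS6": ("late-upregulation", (1.0, 1.0, 1.0, 1.1, 1.4, 2.0, 2.5, 2.8)),
    "Sphk1": ("transient", (1.0, 1.2, 1.5, 1.8, 1.6, 1.3, 1.1, 1.0)),
    "Sphk2": ("transient", (1.0, 1.0, 0.95, 0.9, 0.8, 0.7, 0.75, 0.8)),
    "Ugcg": ("late-upregulation", (1.0, 1.0, 1.0, 1.05, 1.3, 1.8, 2.2, 2.0)),
    "Sms1": ("transient", (1.0, 1.0, 1.1, 1.3, 1.6, 1.5, 1.3, 1.2)),
    "Sms2": ("transient", (1.0, 1.0, 0.95, 0.85, 0.7, 0.6, 0.65, 0.7)),
    "Smpd1": ("late-upregulation", (1.0, 1.0, 1.0, 1.2, 1.5, 2.2, 3.0, 3.2)),
    "Cerk": ("transient", (1.0, 1.1, 1.3, 1.6, 1.9, 1.7, 1.4, 1.2)),
    "Degs1": ("late-upregulation", (1.0, 1.0, 1.0, 1.1, 1.25, 1.6, 1.9, 2.1)),
}


def default_input_profiles(condition: str) -> dict[str, ProfileSpec]:
    """Default input-lipid and gene profiles for one condition."""
    specs: dict[str, ProfileSpec] = {}
    if condition == "control":
        for name, level in _CONTROL_LIPIDS.items():
            specs[name] = ProfileSpec(name, condition, "constant", (level,) * len(DEFAULT_GRID))
        for gene in _TREATMENT_GENES:
            specs[gene] = ProfileSpec(gene, condition, "constant", (1.0,) * len(DEFAULT_GRID))
    elif condition == "treatment":
        for name, (shape, vals) in _TREATMENT_LIPIDS.items():
            specs[name] = ProfileSpec(name, condition, shape, vals)
        for gene, (shape, vals) in _TREATMENT_GENES.items():
            specs[gene] = ProfileSpec(gene, condition, shape, vals)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    _check_gene_identifiability({g: specs[g] for g in _TREATMENT_GENES}, condition)
    return specs


def _check_gene_identifiability(gene_specs: dict[str, ProfileSpec], condition: str) -> None:
    """Treatment gene shapes must be pairwise non-proportional over the grid."""
    if condition != "treatment":
        return
    names = list(gene_specs)
    for i, a in enumerate(names):
        va = np.array(gene_specs[a].values)
        for b in names[i + 1:]:
            vb = np.array(gene_specs[b].values)
            ratio = va / vb
            if np.ptp(ratio) < 1e-9 * np.abs(ratio).max():
                raise ValueError(f"gene profiles {a} and {b} are proportional "
                                 "(confounded rate constants)")


@dataclass
class SyntheticTruth:
    """Everything that determines a synthetic dataset, given the network."""

    params: RateParams
    profiles: dict[tuple[str, str], ProfileSpec]
    x0: np.ndarray | None = None  # None -> control steady state
    noise_frac_sem: float = 0.25
    n_bio: int = 3
    n_tech: int = 3
    seed: int = 0

    @classmethod
    def default(cls, network: ReactionNetwork, params: RateParams | None = None,
                **overrides) -> "SyntheticTruth":
        from .network import load_reference_params

        params = params or load_reference_params(network)
        profiles = {}
        for cond in ("control", "treatment"):
            for name, spec in default_input_profiles(cond).items():
                profiles[(name, cond)] = spec
        return cls(params=params, profiles=profiles, **overrides)

    @property
    def n_replicates(self) -> int:
        return self.n_bio * self.n_tech

    def describe(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "x0": None if self.x0 is None else list(map(float, self.x0)),
            "noise_frac_sem": self.noise_frac_sem,
            "n_bio": self.n_bio,
            "n_tech": self.n_tech,
            "seed": self.seed,
            "profiles": {f"{n}/{c}": list(p.values) for (n, c), p in sorted(self.profiles.items())},
        }


def control_steady_state(network: ReactionNetwork, params: RateParams,
                         truth_or_dataset) -> np.ndarray:
    """Exact steady state of the control condition (linear solve, frozen inputs)."""
    if isinstance(truth_or_dataset, ConditionDataset):
        inputs0 = truth_or_dataset.inputs_at(0.0, "control")
    else:
        from .network import InputVector

        profiles = truth_or_dataset.profiles
        lipids = np.array([profiles[(n, "control")].values[0] for n in network.catalog.input_lipids])
        inputs0 = InputVector(lipids, np.ones(len(network.catalog.gene_inputs)))
    A, u = network.linearize(inputs0, params)
    return np.linalg.solve(A, -u)


def _input_dataset(network: ReactionNetwork, truth: SyntheticTruth) -> ConditionDataset:
    """Noise-free dataset holding only the input/gene courses (states filled later)."""
    courses = {}
    for (name, cond), spec in truth.profiles.items():
        courses[(name, cond)] = spec.as_timecourse()
    # placeholder state courses so ConditionDataset validation passes
    grid = np.array(DEFAULT_GRID)
    for s in network.catalog.dynamic_species:
        for cond in ("control", "treatment"):
            courses[(s, cond)] = TimeCourse(s, cond, grid, np.zeros_like(grid))
    return ConditionDataset(network.catalog, courses)


def generate_dataset(network: ReactionNetwork, truth: SyntheticTruth,
                     rng: np.random.Generator | None = None) -> ConditionDataset:
    """Simulate the model under both conditions and wrap it as measured data.

    With ``noise_frac_sem = 0`` and a single replicate the returned dataset
    equals the model trajectory at the grid times exactly (SEM = 0).
    Otherwise replicate tables with multiplicative lognormal noise are drawn
    and pushed through the standard preprocessing (outlier filter + averaging).
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    scaffold = _input_dataset(network, truth)
    x0 = truth.x0 if truth.x0 is not None else control_steady_state(network, truth.params, truth)
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("synthetic initial state has negative entries")

    grid = np.array(DEFAULT_GRID)
    true_courses: dict[tuple[str, str], TimeCourse] = {}
    for cond in ("control", "treatment"):
        traj = simulate(network, truth.params, x0, scaffold, cond, t_grid=grid,
                        rtol=1e-10, atol=1e-12, method="LSODA")
        for j, s in enumerate(network.catalog.dynamic_species):
            true_courses[(s, cond)] = TimeCourse(s, cond, grid, traj.states[:, j])
    for (name, cond), spec in truth.profiles.items():
        true_courses[(name, cond)] = spec.as_timecourse()

    if truth.noise_frac_sem == 0 and truth.n_replicates == 1:
        return ConditionDataset(network.catalog, true_courses)

    nrep = truth.n_replicates
    cv_rep = truth.noise_frac_sem * np.sqrt(nrep)
    sigma = np.sqrt(np.log1p(cv_rep**2))
    tables: dict[tuple[str, str], ReplicateTable] = {}
    for (name, cond) in sorted(true_courses):
        if name in network.catalog.gene_inputs and cond == "control":
            continue  # control gene folds are a convention (exactly 1), not a measurement
        tc = true_courses[(name, cond)]
        rows = []
        for t, mu in zip(tc.times, tc.values):
            # mean-preserving lognormal multipliers
            mult = np.exp(sigma * rng.standard_normal(nrep) - 0.5 * sigma**2)
            for r, m in enumerate(mult):
                rows.append({"time_hr": t, "replicate_bio": r // truth.n_tech + 1,
                             "replicate_tech": r % truth.n_tech + 1, "value": mu * m})
        tables[(name, cond)] = ReplicateTable(pd.DataFrame(rows), name, cond)
    return ConditionDataset.from_replicates(network.catalog, tables)
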