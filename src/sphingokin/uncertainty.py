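"""Replicate-noise propagation into rate-constant uncertainty by resampling.

The measured courses carry a per-point SEM from the replicate structure.  The
procedure: (1) take the per-point SEMs; (2) draw a candidate dataset
mean + SEM * z with z ~ N(0,1) i.i.d. per point (negative draws floored at
zero); (3) run the full two-step estimation on the candidate; (4) repeat k
times (k = 10 by default); (5) summarise the spread of each rate constant
across the k estimates.

"Spread" is reported both as the standard deviation of the k estimates and as
sd/sqrt(k); the sd of re-estimates is the headline number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import FitConfig, two_step_fit
from .network import ReactionNetwork
from .timecourse import ConditionDataset, TimeCourse

__all__ = ["ResamplingConfig", "UncertaintyResult", "perturb_dataset", "parameter_sem"]


@dataclass
class ResamplingConfig:
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least k = 2 resampled datasets")


def perturb_dataset(dataset: ConditionDataset, rng: np.random.Generator) -> ConditionDataset:
    """One candidate dataset: every measured course gets mean + SEM * z.

    Metabolite, input-lipid and gene courses are all perturbed; the
    conventional control gene folds (identically 1, SEM 0) are left untouched.
    Negative candidates are floored at 0 to stay physical.
    """
    cat = dataset.catalog
    courses = {}
    for (name, cond), tc in sorted(dataset.courses.items()):
        if name in cat.gene_inputs and cond == "control":
            courses[(name, cond)] = tc
            continue
        if tc.sem is None:
            raise ValueError(f"course {name!r}/{cond!r} carries no SEM")
        z = rng.standard_normal(tc.values.shape)
        vals = np.maximum(tc.values + tc.sem * z, 0.0)
        courses[(name, cond)] = TimeCourse(name, cond, tc.times.copy(), vals, tc.sem.copy())
    return ConditionDataset(cat, courses)


@dataclass
class UncertaintyResult:
    """Point estimate plus the spread of the k re-estimates."""

    point: pd.Series
    estimates: pd.DataFrame          # k rows x parameters
    sd: pd.Series                    # spread across the k re-estimates
    sem: pd.Series                   # sd / sqrt(k)
    n_failed: int
    seed: int

    def fractional_sd(self) -> pd.Series:
        """sd relative to the point estimate (NaN where the point is 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = self.sd / self.point.replace(0.0, np.nan)
        return frac

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.point, "sd": self.sd, "sem": self.sem,
                             "fractional_sd": self.fractional_sd()})


def parameter_sem(network: ReactionNetwork, dataset: ConditionDataset,
                  config: ResamplingConfig | None = None,
                  fit_config: FitConfig | None = None,
                  point_fit=None) -> UncertaintyResult:
    """Propagate the data SEM into per-parameter spread via k refits.

    Candidate fits that fail are excluded and counted; more than k/2 failures
    abort with diagnostics.  With SEM identically zero in the data, all
    candidates coincide and the spread is exactly zero.
    """
    config = config or ResamplingConfig()
    fit_config = fit_config or FitConfig()
    rng = np.random.default_rng(config.seed)

    if point_fit is None:
        point_fit = two_step_fit(network, dataset, fit_config)
    point = point_fit.params_series()

    rows, failures = [], []
    for i in range(config.k):
        candidate = perturb_dataset(dataset, rng)
        try:
            fit = two_step_fit(network, candidate, fit_config)
            rows.append(fit.params_series())
        except Exception as exc:  # noqa: BLE001 - failure accounting is the contract
            failures.append(f"replicate {i}: {exc}")
        if len(failures) > config.k / 2:
            raise RuntimeError(
                "resampling aborted, too many fit failures:\n" + "\n".join(failures)
            )
    estimates = pd.DataFrame(rows).reset_index(drop=True)
    sd = estimates.std(ddof=1)
    return UncertaintyResult(point=point, estimates=estimates, sd=sd,
                             sem=sd / np.sqrt(len(estimates)), n_failed=len(failures),
                             seed=config.seed)
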