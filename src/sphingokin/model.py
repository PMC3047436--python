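"""Model/results front-end for the sphingolipid kinetics pipeline.

`SphingolipidKinetics` binds the reaction network to a dual-condition dataset;
`fit()` runs the two-step estimation and returns `KineticFitResults`, which
carries the rate constants, resampling-based uncertainties, diagnostics and a
`summary()` table, and from which simulation, sensitivity and time-scale
analyses are launched.

Example
-------
>>> import sphingokin as sk
>>> net = sk.load_default_network()
>>> truth = sk.SyntheticTruth.default(net, noise_frac_sem=0.0, n_bio=1, n_tech=1)
>>> data = sk.generate_dataset(net, truth)
>>> res = sk.SphingolipidKinetics(data, network=net).fit()
>>> round(res.params["kf6"], 3)
0.528
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .analysis import (DEFAULT_RATIOS, SensitivityResult, TimescaleResult,
                       sensitivity_scan, timescale_classification)
from .estimation import (FitConfig, FitResult, build_regression_system, linear_estimate,
                         two_step_fit)
from .network import RateParams, ReactionNetwork, load_default_network
from .simulate import Trajectory, simulate
from .timecourse import ConditionDataset
from .uncertainty import ResamplingConfig, UncertaintyResult, parameter_sem

__all__ = ["SphingolipidKinetics", "KineticFitResults"]


class SphingolipidKinetics:
    """Mass-action kinetic model of the C16 sphingolipid branch, bound to data.

    Parameters
    ----------
    dataset : ConditionDataset
        Paired control/treatment mean +- SEM courses for the 9 dynamic
        metabolites, 4 input lipids and 9 genes.
    network : ReactionNetwork, optional
        Defaults to the packaged C16 network.
    config : FitConfig, optional
        Estimator settings (bounds, weighting, windows, tolerances).
    """

    def __init__(self, dataset: ConditionDataset, network: ReactionNetwork | None = None,
                 config: FitConfig | None = None):
        self.network = network or load_default_network()
        self.dataset = dataset
        self.config = config or FitConfig()

    @classmethod
    def from_csv(cls, path, network: ReactionNetwork | None = None,
                 config: FitConfig | None = None) -> "SphingolipidKinetics":
        network = network or load_default_network()
        dataset = ConditionDataset.from_csv(network.catalog, path)
        return cls(dataset, network, config)

    def linear_start(self) -> RateParams:
        """Step-1 estimate only (constrained linear least squares)."""
        system = build_regression_system(self.network, self.dataset,
                                         self.config.conditions, self.config.gene_delay)
        return linear_estimate(system, self.config)

    def fit(self, tie: tuple[tuple[str, str], ...] = ()) -> "KineticFitResults":
        """Run the two-step estimation; optionally tie enzyme parameter pairs."""
        result = two_step_fit(self.network, self.dataset, self.config, tie=tie)
        return KineticFitResults(self, result)

    def simulate(self, params: RateParams, x0, condition: str, t_grid=None, **kw) -> Trajectory:
        return simulate(self.network, params, x0, self.dataset, condition, t_grid, **kw)


class KineticFitResults:
    """Fitted rate constants with uncertainties, diagnostics and analyses."""

    def __init__(self, model: SphingolipidKinetics, fit: FitResult,
                 uncertainty: UncertaintyResult | None = None):
        self.model = model
        self.fit = fit
        self.uncertainty = uncertainty

    # -- estimates ----------------------------------------------------------

    @property
    def params(self) -> pd.Series:
        return self.fit.params_series()

    @property
    def rate_params(self) -> RateParams:
        return self.fit.params

    @property
    def x0(self) -> dict[str, np.ndarray]:
        return self.fit.x0

    @property
    def objective(self) -> float:
        return self.fit.objective

    @property
    def bse(self) -> pd.Series | None:
        """Resampling spread of each constant (None until resample() is run)."""
        return None if self.uncertainty is None else self.uncertainty.sd

    # -- uncertainty --------------------------------------------------------

    def resample(self, k: int = 10, seed: int = 0,
                 fit_config: FitConfig | None = None) -> UncertaintyResult:
        """SEM-resampling uncertainty (k refits on perturbed datasets)."""
        self.uncertainty = parameter_sem(
            self.model.network, self.model.dataset, ResamplingConfig(k=k, seed=seed),
            fit_config or self.model.config, point_fit=self.fit,
        )
        return self.uncertainty

    # -- downstream analyses -------------------------------------------------

    def predict(self, condition: str, t_grid=None, **kw) -> Trajectory:
        """Model trajectory under one condition at the fitted estimates."""
        return self.model.simulate(self.rate_params, self.fit.x0[condition], condition,
                                   t_grid, **kw)

    def sensitivity(self, param_name: str, ratios=DEFAULT_RATIOS, **kw) -> SensitivityResult:
        return sensitivity_scan(self.model.network, self.rate_params, self.model.dataset,
                                param_name, ratios, **kw)

    def timescales(self, **kw) -> TimescaleResult:
        return timescale_classification(self.model.network, self.rate_params,
                                        self.model.dataset, **kw)

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = []
        net = self.model.network
        title = "C16 sphingolipid kinetics — two-step mass-action fit"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"network: {net.name or 'custom'}  "
                     f"({net.n_species} species, {net.n_reactions} reactions, "
                     f"{net.n_params} rate constants)")
        lines.append(f"conditions fitted: {', '.join(self.model.config.conditions)}")
        lines.append(f"observations: {self.fit.n_obs}   objective: {self.fit.objective:.6g}")
        lines.append(f"converged: {self.fit.success}   ({self.fit.message})")
        if self.fit.tied_pairs:
            lines.append("tied pairs: " + ", ".join("=".join(p) for p in self.fit.tied_pairs))
        lines.append("")
        header = f"{'parameter':<10}{'estimate':>14}" + (
            f"{'resample sd':>14}" if self.uncertainty is not None else "")
        lines.append(header)
        lines.append("-" * len(header))
        for name in net.param_names:
            row = f"{name:<10}{self.params[name]:>14.4e}"
            if self.uncertainty is not None:
                row += f"{self.uncertainty.sd[name]:>14.4e}"
            lines.append(row)
        lines.append("")
        lines.append("per-species normalised RMS fit error:")
        for sp, v in self.fit.per_species_error.items():
            lines.append(f"  {sp:<14}{v:.4g}")
        return "\n".join(lines)

    def params_frame(self) -> pd.DataFrame:
        cfg = self.model.config
        df = pd.DataFrame({"name": list(self.model.network.param_names)})
        df["value"] = df["name"].map(self.params)
        df["lower"] = 0.0
        df["upper"] = cfg.upper_bound
        df["sem"] = df["name"].map(self.bse) if self.bse is not None else np.nan
        return df

    def plot_fit(self, conditions=("control", "treatment"), n_dense: int = 121):
        """Overlay fitted trajectories on the measured courses (matplotlib)."""
        import matplotlib.pyplot as plt

        species = self.model.network.catalog.dynamic_species
        fig, axes = plt.subplots(3, 3, figsize=(11, 8), sharex=True)
        grid = self.model.dataset.grid(conditions[0])
        t_dense = np.linspace(grid[0], grid[-1], n_dense)
        colors = {"control": "tab:blue", "treatment": "tab:red"}
        for cond in conditions:
            traj = self.predict(cond, t_grid=t_dense)
            for ax, sp in zip(axes.ravel(), species):
                tc = self.model.dataset.course(sp, cond)
                ax.errorbar(tc.times, tc.values, yerr=tc.sem, fmt="o", ms=3,
                            color=colors.get(cond), label=f"{cond} data")
                ax.plot(t_dense, traj.series(sp), color=colors.get(cond), lw=1)
                ax.set_title(sp, fontsize=9)
        axes[0, 0].legend(fontsize=7)
        for ax in axes[-1]:
            ax.set_xlabel("time (hr)")
        fig.tight_layout()
        return fig
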