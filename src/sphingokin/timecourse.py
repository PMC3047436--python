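"""Time-course containers, replicate preprocessing and input interpolation.

Experimental design emulated here: 8 samples at 0, 0.5, 1, 2, 4, 8, 12, 24 hr
under two conditions (control and endotoxin treatment), with 3 biological x 3
technical replicates per point.  Preprocessing removes per-time-point outliers
with an iterative Grubbs (studentized extreme deviation) test and averages the
survivors into mean +- SEM.  Gene inputs are mRNA fold-changes used as protein
proxies with a 3-hour translation delay, p(t) = g(t - 3); the control
condition uses fold 1 for every gene by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import InputVector, SpeciesCatalog

__all__ = [
    "DEFAULT_GRID",
    "GENE_DELAY_HR",
    "TimeCourse",
    "ReplicateTable",
    "ConditionDataset",
    "remove_outliers",
    "average_replicates",
    "interpolate_input",
    "delayed_gene",
]

DEFAULT_GRID = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])
GENE_DELAY_HR = 3.0
CONDITIONS = ("control", "treatment")


@dataclass
class TimeCourse:
    """Mean +- SEM course of one quantity under one condition."""

    name: str
    condition: str
    times: np.ndarray
    values: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sem is None:
            self.sem = np.zeros_like(self.values)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (self.times.shape == self.values.shape == self.sem.shape):
            raise ValueError(f"{self.name}: times/values/sem length mismatch")
        if self.times.size == 0:
            raise ValueError(f"{self.name}: empty time course")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.name}: times must be strictly increasing")
        if np.any(self.sem < 0):
            raise ValueError(f"{self.name}: negative SEM")

    def interpolate(self, t):
        """Piecewise-linear value at *t*; constant beyond the measured range."""
        return np.interp(t, self.times, self.values)

    def delayed(self, t, delay: float = GENE_DELAY_HR):
        """Delayed evaluation, p(t) = g(t - delay); holds g(t0) for t < t0 + delay."""
        return self.interpolate(np.asarray(t) - delay)

    def replace_values(self, values, sem=None) -> "TimeCourse":
        return TimeCourse(self.name, self.condition, self.times.copy(), values,
                          self.sem.copy() if sem is None else sem)


def interpolate_input(tc: TimeCourse, t):
    """Module-level alias of :meth:`TimeCourse.interpolate`."""
    return tc.interpolate(t)


def delayed_gene(tc: TimeCourse, t, delay: float = GENE_DELAY_HR):
    """Protein-activity proxy from a gene fold course with translation delay."""
    return tc.delayed(t, delay)


class ReplicateTable:
    """Replicate-level measurements of one quantity under one condition.

    Backed by a DataFrame with columns ``time_hr, replicate_bio,
    replicate_tech, value``.
    """

    COLUMNS = ("time_hr", "replicate_bio", "replicate_tech", "value")

    def __init__(self, frame: pd.DataFrame, name: str = "", condition: str = ""):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"replicate table missing columns {missing}")
        if len(frame) == 0:
            raise ValueError("empty replicate table")
        self.frame = frame.reset_index(drop=True)
        self.name = name
        self.condition = condition

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frame["time_hr"].unique())

    def values_at(self, t: float) -> np.ndarray:
        return self.frame.loc[self.frame["time_hr"] == t, "value"].to_numpy(dtype=float)


def _grubbs_critical(n: int, alpha: float) -> float:
    # two-sided Grubbs critical value for the max studentized deviation
    tcrit = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(tcrit**2 / (n - 2 + tcrit**2))


def remove_outliers(table: ReplicateTable, alpha: float = 0.05) -> ReplicateTable:
    """Iterative per-time-point Grubbs test at level *alpha*.

    Time points with fewer than 3 replicates are returned unchanged; at most
    floor(n/3) values are removed per time point.
    """
    keep_parts = []
    for t in table.times:
        sub = table.frame[table.frame["time_hr"] == t].copy()
        n0 = len(sub)
        max_remove = n0 // 3
        removed = 0
        while removed < max_remove and len(sub) >= 3:
            x = sub["value"].to_numpy(dtype=float)
            s = x.std(ddof=1)
            if s == 0:
                break
            dev = np.abs(x - x.mean())
            g = dev.max() / s
            if g <= _grubbs_critical(len(x), alpha):
                break
            sub = sub.drop(sub.index[int(np.argmax(dev))])
            removed += 1
        keep_parts.append(sub)
    return ReplicateTable(pd.concat(keep_parts, ignore_index=True), table.name, table.condition)


def average_replicates(table: ReplicateTable, name: str | None = None,
                       condition: str | None = None) -> TimeCourse:
    """Mean and SEM (sd/sqrt(n), ddof=1; 0 for a single replicate) per time point."""
    times = table.times
    means = np.empty(times.size)
    sems = np.empty(times.size)
    for i, t in enumerate(times):
        x = table.values_at(t)
        if x.size == 0:
            raise ValueError(f"no surviving replicates at t = {t} hr")
        means[i] = x.mean()
        sems[i] = 0.0 if x.size == 1 else x.std(ddof=1) / np.sqrt(x.size)
    return TimeCourse(name or table.name, condition or table.condition, times, means, sems)


class ConditionDataset:
    """Paired control/treatment time-courses for every model quantity.

    Holds one :class:`TimeCourse` per (name, condition) for the 9 dynamic
    species, 4 input lipids and 9 genes.  Control gene courses may be omitted
    on construction; they are filled with the conventional fold of 1 on the
    control grid.
    """

    def __init__(self, catalog: SpeciesCatalog, courses: dict[tuple[str, str], TimeCourse]):
        self.catalog = catalog
        self.courses = dict(courses)
        self._fill_control_genes()
        self._validate()

    def _fill_control_genes(self) -> None:
        grid = None
        for (name, cond), tc in self.courses.items():
            if cond == "control":
                grid = tc.times
                break
        if grid is None:
            raise ValueError("dataset contains no control courses")
        for g in self.catalog.gene_inputs:
            if ("control" in CONDITIONS) and (g, "control") not in self.courses:
                self.courses[(g, "control")] = TimeCourse(g, "control", grid, np.ones_like(grid))

    def _validate(self) -> None:
        for cond in CONDITIONS:
            grid = None
            for name in self.catalog.all_names:
                tc = self.courses.get((name, cond))
                if tc is None:
                    raise ValueError(f"missing time course for {name!r} under {cond!r}")
                if grid is None:
                    grid = tc.times
                elif not np.array_equal(tc.times, grid):
                    raise ValueError(f"{name!r}/{cond!r} is not on the shared time grid")
            for g in self.catalog.gene_inputs:
                tc = self.courses[(g, "control")]
                if not np.allclose(tc.values, 1.0):
                    raise ValueError(f"control gene folds must be 1 (offending gene: {g})")

    # -- accessors -----------------------------------------------------------

    def course(self, name: str, condition: str) -> TimeCourse:
        try:
            return self.courses[(name, condition)]
        except KeyError:
            raise KeyError(f"no course for {name!r} under {condition!r}") from None

    def grid(self, condition: str = "control") -> np.ndarray:
        return self.course(self.catalog.dynamic_species[0], condition).times

    def state_matrix(self, condition: str) -> np.ndarray:
        """Measured dynamic-species values, shape (n_times, 9) in catalog order."""
        return np.column_stack(
            [self.course(s, condition).values for s in self.catalog.dynamic_species]
        )

    def state_sem_matrix(self, condition: str) -> np.ndarray:
        return np.column_stack(
            [self.course(s, condition).sem for s in self.catalog.dynamic_species]
        )

    def inputs_at(self, t: float, condition: str, delay: float = GENE_DELAY_HR) -> InputVector:
        """Interpolated input lipids and (delayed) gene folds at time *t*.

        The control condition forces every gene fold to 1 regardless of the
        stored course.
        """
        lipids = np.array([self.course(n, condition).interpolate(t) for n in self.catalog.input_lipids])
        if condition == "control":
            genes = np.ones(len(self.catalog.gene_inputs))
        else:
            genes = np.array([self.course(g, condition).delayed(t, delay) for g in self.catalog.gene_inputs])
        return InputVector(lipids, genes)

    # -- I/O ------------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (name, cond), tc in sorted(self.courses.items()):
            for t, v, s in zip(tc.times, tc.values, tc.sem):
                rows.append({"time_hr": t, "species": name, "condition": cond,
                             "mean": v, "sem": s})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, catalog: SpeciesCatalog, frame: pd.DataFrame) -> "ConditionDataset":
        courses = {}
        for (name, cond), sub in frame.groupby(["species", "condition"]):
            sub = sub.sort_values("time_hr")
            courses[(name, cond)] = TimeCourse(
                name, cond, sub["time_hr"].to_numpy(), sub["mean"].to_numpy(),
                sub["sem"].to_numpy() if "sem" in sub else None,
            )
        return cls(catalog, courses)

    @classmethod
    def from_csv(cls, catalog: SpeciesCatalog, path) -> "ConditionDataset":
        return cls.from_frame(catalog, pd.read_csv(path))

    @classmethod
    def from_replicates(cls, catalog: SpeciesCatalog, tables: dict[tuple[str, str], ReplicateTable],
                        alpha: float = 0.05, outlier_filter: bool = True) -> "ConditionDataset":
        """Preprocess replicate tables (outlier removal + averaging) into a dataset."""
        courses = {}
        for (name, cond), table in tables.items():
            if outlier_filter:
                table = remove_outliers(table, alpha)
            courses[(name, cond)] = average_replicates(table, name, cond)
        return cls(catalog, courses)
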