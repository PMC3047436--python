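"""Mass-action reaction network for the C16 branch of sphingolipid metabolism.

The model tracks 9 dynamic metabolites (dihydro- and regular ceramide species
and their 1-phosphate, sphingomyelin and glucosylceramide derivatives) driven
by 4 measured input lipids (sphinganine, palmitoyl-CoA, C16 diacylglycerol,
C16 glycerophosphocholine) and 9 enzyme activities proxied by delayed mRNA
fold-changes.  Every reaction follows the law of mass action under the
assumption that substrate concentrations are far below the enzymes' Michaelis
constants, so each flux is a rate constant times the product of its reactant
(and enzyme-fold) concentrations.  Four sphingomyelin-synthase reactions are
reversible; all fluxes are therefore linear in the 29 rate constants, which is
what the first (matrix) step of parameter estimation exploits.

Units: time in hours, concentrations in pmol/ug-DNA, gene folds dimensionless;
rate constants carry whatever reciprocal units make each flux pmol/ug-DNA/hr.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SpeciesCatalog",
    "Reaction",
    "RateParams",
    "InputVector",
    "ReactionNetwork",
    "load_default_network",
    "load_reference_params",
]


@dataclass(frozen=True)
class SpeciesCatalog:
    """Fixed naming and ordering of model quantities.

    The order of ``dynamic_species`` defines state-vector indexing everywhere
    in the package (ODE right-hand sides, trajectories, Jacobians).
    """

    dynamic_species: tuple[str, ...]
    input_lipids: tuple[str, ...]
    gene_inputs: tuple[str, ...]

    def __post_init__(self) -> None:
        names = list(self.dynamic_species) + list(self.input_lipids) + list(self.gene_inputs)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate names in species catalog: {dupes}")

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.dynamic_species + self.input_lipids + self.gene_inputs

    def index_of(self, name: str) -> int:
        """Position of *name* in the concatenated (state, lipids, genes) vector."""
        try:
            return self.all_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species/input/gene name: {name!r}") from None


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.

    ``reactants``/``products`` hold every concentration factor of the
    forward/backward rate except the enzyme, which (if present) multiplies
    both directions.  Only dynamic species contribute stoichiometry.
    """

    id: int
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    forward_param: str
    enzyme: str | None = None
    backward_param: str | None = None

    @property
    def reversible(self) -> bool:
        return self.backward_param is not None

    @property
    def forward_factors(self) -> tuple[str, ...]:
        return self.reactants + ((self.enzyme,) if self.enzyme else ())

    @property
    def backward_factors(self) -> tuple[str, ...]:
        return self.products + ((self.enzyme,) if self.enzyme else ())


class RateParams:
    """The nonnegative rate constants of a network, in canonical order.

    Behaves like an ordered name -> value mapping backed by a numpy vector.
    """

    def __init__(self, names: Sequence[str], values: Iterable[float]):
        self.names = tuple(names)
        self.values = np.asarray(list(values), dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("parameter names and values must have equal length")
        if np.any(self.values < 0):
            bad = [n for n, v in zip(self.names, self.values) if v < 0]
            raise ValueError(f"rate constants must be nonnegative; offending: {bad}")
        self._index = {n: i for i, n in enumerate(self.names)}

    @classmethod
    def from_dict(cls, names: Sequence[str], mapping: Mapping[str, float]) -> "RateParams":
        missing = [n for n in names if n not in mapping]
        if missing:
            raise KeyError(f"missing rate constants: {missing}")
        return cls(names, [mapping[n] for n in names])

    def __getitem__(self, name: str) -> float:
        return float(self.values[self._index[name]])

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def replace(self, **updates: float) -> "RateParams":
        vals = self.values.copy()
        for name, v in updates.items():
            vals[self._index[name]] = v
        return RateParams(self.names, vals)

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RateParams({self.to_dict()!r})"


@dataclass
class InputVector:
    """Input lipid concentrations and gene fold-changes at one instant."""

    lipids: np.ndarray
    genes: np.ndarray

    def __post_init__(self) -> None:
        self.lipids = np.atleast_1d(np.asarray(self.lipids, dtype=float))
        self.genes = np.atleast_1d(np.asarray(self.genes, dtype=float))

    def validate(self, catalog: SpeciesCatalog) -> None:
        if self.lipids.shape != (len(catalog.input_lipids),):
            raise ValueError("lipid vector has wrong length")
        if self.genes.shape != (len(catalog.gene_inputs),):
            raise ValueError("gene-fold vector has wrong length")
        for names, vec in ((catalog.input_lipids, self.lipids), (catalog.gene_inputs, self.genes)):
            if np.any(vec < 0):
                bad = [n for n, v in zip(names, vec) if v < 0]
                raise ValueError(f"negative input value for {bad}")


class ReactionNetwork:
    """Reaction list, stoichiometry and rate laws, with fast vectorised kernels.

    The internal representation concatenates state, input lipids and gene
    folds into one factor vector ``z`` (padded with a constant 1.0), and
    encodes each rate term as a product over up to three indices into ``z``.
    """

    MAX_FACTORS = 3

    def __init__(self, catalog: SpeciesCatalog, reactions: Sequence[Reaction], name: str = ""):
        self.name = name
        self.catalog = catalog
        self.reactions = tuple(sorted(reactions, key=lambda r: r.id))
        self._validate()
        self._build_index_arrays()

    # -- construction -------------------------------------------------------

    def _validate(self) -> None:
        cat = self.catalog
        seen_params: set[str] = set()
        for rxn in self.reactions:
            for nm in rxn.reactants + rxn.products + ((rxn.enzyme,) if rxn.enzyme else ()):
                cat.index_of(nm)  # raises KeyError on unknown names
            for p in (rxn.forward_param, rxn.backward_param):
                if p is not None:
                    if p in seen_params:
                        raise ValueError(f"parameter {p} used by more than one reaction")
                    seen_params.add(p)
            if len(rxn.forward_factors) > self.MAX_FACTORS or len(rxn.backward_factors) > self.MAX_FACTORS:
                raise ValueError(f"reaction {rxn.id} has too many rate factors")

    def _build_index_arrays(self) -> None:
        cat = self.catalog
        nsp = len(cat.dynamic_species)
        nrx = len(self.reactions)
        self.n_species = nsp
        self.n_reactions = nrx
        self._one = len(cat.all_names)  # index of the 1.0 padding slot in z

        # canonical parameter order: all forward constants in reaction order,
        # then backward constants in reaction order
        self.param_names: tuple[str, ...] = tuple(
            [r.forward_param for r in self.reactions]
            + [r.backward_param for r in self.reactions if r.reversible]
        )
        self.n_params = len(self.param_names)

        fwd = np.full((nrx, self.MAX_FACTORS), self._one, dtype=np.intp)
        bwd = np.full((nrx, self.MAX_FACTORS), self._one, dtype=np.intp)
        S = np.zeros((nsp, nrx), dtype=int)
        sp_index = {n: i for i, n in enumerate(cat.dynamic_species)}
        for j, rxn in enumerate(self.reactions):
            for k, nm in enumerate(rxn.forward_factors):
                fwd[j, k] = cat.index_of(nm)
            if rxn.reversible:
                for k, nm in enumerate(rxn.backward_factors):
                    bwd[j, k] = cat.index_of(nm)
            for nm in rxn.reactants:
                if nm in sp_index:
                    S[sp_index[nm], j] -= 1
            for nm in rxn.products:
                if nm in sp_index:
                    S[sp_index[nm], j] += 1
        self._fwd_idx = fwd
        self._bwd_idx = bwd
        self._S = S

        # map the 29-vector onto per-reaction forward/backward constants
        pidx = {n: i for i, n in enumerate(self.param_names)}
        self._fwd_param_pos = np.array([pidx[r.forward_param] for r in self.reactions], dtype=np.intp)
        self._rev_rxn_rows = np.array([j for j, r in enumerate(self.reactions) if r.reversible], dtype=np.intp)
        self._bwd_param_pos = np.array(
            [pidx[r.backward_param] for r in self.reactions if r.reversible], dtype=np.intp
        )
        # reaction index of each parameter (for the 9 x n_params design block)
        rxn_of_param = np.empty(self.n_params, dtype=np.intp)
        rxn_of_param[self._fwd_param_pos] = np.arange(nrx)
        rxn_of_param[self._bwd_param_pos] = self._rev_rxn_rows
        self._rxn_of_param = rxn_of_param
        self._is_backward = np.zeros(self.n_params, dtype=bool)
        self._is_backward[self._bwd_param_pos] = True
        self.irreversible_mask = np.array([not r.reversible for r in self.reactions])

    @classmethod
    def from_yaml(cls, path=None) -> "ReactionNetwork":
        """Load a network definition; defaults to the packaged C16 network."""
        if path is None:
            with resources.files("sphingokin.data").joinpath("c16_network.yaml").open() as fh:
                doc = yaml.safe_load(fh)
        else:
            with open(path) as fh:
                doc = yaml.safe_load(fh)
        catalog = SpeciesCatalog(
            tuple(doc["species"]), tuple(doc["input_lipids"]), tuple(doc["genes"])
        )
        reactions = []
        for rec in doc["reactions"]:
            reversible = bool(rec.get("reversible", False))
            if reversible and "backward_param" not in rec:
                raise ValueError(f"reversible reaction {rec['id']} lacks a backward parameter")
            reactions.append(
                Reaction(
                    id=int(rec["id"]),
                    reactants=tuple(rec["reactants"]),
                    products=tuple(rec.get("products", [])),
                    enzyme=rec.get("enzyme"),
                    forward_param=rec["forward_param"],
                    backward_param=rec.get("backward_param") if reversible else None,
                )
            )
        return cls(catalog, reactions, name=doc.get("name", ""))

    # -- rate-law kernels ----------------------------------------------------

    def _z(self, state, lipids, genes) -> np.ndarray:
        z = np.empty(self._one + 1)
        n = self.n_species
        z[:n] = state
        z[n : n + len(self.catalog.input_lipids)] = lipids
        z[n + len(self.catalog.input_lipids) : self._one] = genes
        z[self._one] = 1.0
        return z

    def _check(self, state, inputs: InputVector) -> tuple[np.ndarray, InputVector]:
        state = np.atleast_1d(np.asarray(state, dtype=float))
        if state.shape != (self.n_species,):
            raise ValueError(
                f"state must have length {self.n_species} "
                f"(order: {self.catalog.dynamic_species})"
            )
        if np.any(state < 0):
            bad = [n for n, v in zip(self.catalog.dynamic_species, state) if v < 0]
            raise ValueError(f"negative concentration for {bad}")
        inputs.validate(self.catalog)
        return state, inputs

    def _split_params(self, params: RateParams) -> tuple[np.ndarray, np.ndarray]:
        b = params.values
        kf = b[self._fwd_param_pos]
        kb = np.zeros(self.n_reactions)
        kb[self._rev_rxn_rows] = b[self._bwd_param_pos]
        return kf, kb

    def _term_products(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return z[self._fwd_idx].prod(axis=1), z[self._bwd_idx].prod(axis=1)

    def flux_vector(self, state, inputs: InputVector, params: RateParams, *, validate: bool = True) -> np.ndarray:
        """Signed fluxes v_1..v_25 (pmol/ug-DNA/hr); reversible ones may be negative."""
        if validate:
            state, inputs = self._check(state, inputs)
        z = self._z(state, inputs.lipids, inputs.genes)
        kf, kb = self._split_params(params)
        pf, pb = self._term_products(z)
        return kf * pf - kb * pb

    def rhs(self, state, inputs: InputVector, params: RateParams, *, validate: bool = True) -> np.ndarray:
        """Time derivatives of the 9 dynamic species: S @ flux_vector."""
        return self._S @ self.flux_vector(state, inputs, params, validate=validate)

    def stoichiometry_matrix(self) -> np.ndarray:
        """9 x 25 integer net-stoichiometry matrix (species x reactions)."""
        return self._S.copy()

    def basis_fluxes(self, state, inputs: InputVector, *, validate: bool = True) -> np.ndarray:
        """Per-parameter regressors: d(flux of its reaction)/d(parameter).

        Forward entries are the forward factor products; backward entries carry
        the negative sign of the reverse term, so that for any parameter vector
        ``b``: ``design_block(...) @ b == rhs(...)``.
        """
        if validate:
            state, inputs = self._check(state, inputs)
        z = self._z(state, inputs.lipids, inputs.genes)
        pf, pb = self._term_products(z)
        basis = np.where(self._is_backward, -pb[self._rxn_of_param], pf[self._rxn_of_param])
        return basis

    def design_block(self, state, inputs: InputVector, *, validate: bool = True) -> np.ndarray:
        """9 x n_params block D with D @ b == rhs(state, inputs, b) for all b."""
        basis = self.basis_fluxes(state, inputs, validate=validate)
        return self._S[:, self._rxn_of_param] * basis[None, :]

    def linearize(self, inputs: InputVector, params: RateParams) -> tuple[np.ndarray, np.ndarray]:
        """Exact (A, u) with rhs(x) = A x + u at frozen inputs.

        Every flux involves at most one dynamic species, so the system is
        linear in the state and this decomposition is exact, not a local
        approximation.
        """
        inputs.validate(self.catalog)
        n = self.n_species
        u = self.rhs(np.zeros(n), inputs, params, validate=False)
        A = np.empty((n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = 1.0
            A[:, j] = self.rhs(e, inputs, params, validate=False) - u
        return A, u

    def make_params(self, values) -> RateParams:
        """Build a RateParams in this network's canonical order."""
        if isinstance(values, Mapping):
            return RateParams.from_dict(self.param_names, values)
        return RateParams(self.param_names, values)


def load_default_network() -> ReactionNetwork:
    return ReactionNetwork.from_yaml()


def load_reference_params(network: ReactionNetwork | None = None, with_sem: bool = False):
    """The published rate-constant estimates shipped with the package.

    These are the reference values for the C16 network (29 constants spanning
    ~5e-5 to 13 in model units) and serve as the default ground truth of the
    synthetic-data generator.
    """
    import csv

    network = network or load_default_network()
    with resources.files("sphingokin.data").joinpath("reference_params.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    values = {r["name"]: float(r["value"]) for r in rows}
    params = network.make_params(values)
    if with_sem:
        sems = {r["name"]: float(r["sem"]) for r in rows}
        return params, sems
    return params
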