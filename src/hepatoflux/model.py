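"""Core data model for constraint-based metabolic networks.

A :class:`MetabolicModel` is a compartmentalized stoichiometric network:
metabolites, reactions with flux bounds (mmol/gDW/h), subsystem labels and
gene-protein-reaction rules.  The stoichiometric matrix S (metabolites x
reactions) together with bounds defines the feasible flux space
``{v : S v = 0, lb <= v <= ub}`` on which all downstream analyses operate.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .gpr import GeneRule, parse_gpr

__all__ = ["Metabolite", "Reaction", "MetabolicModel", "FluxVector"]


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.compartment:
            raise ValueError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    """A reaction: signed stoichiometry over metabolite ids plus flux bounds.

    ``is_exchange`` marks boundary reactions (one-sided stoichiometry that
    imports/exports across the system boundary); these carry no enzymatic
    evidence and are treated specially by context extraction and sampling.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str = "unassigned"
    gpr: GeneRule = field(default_factory=lambda: GeneRule.EMPTY)
    is_exchange: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lb {self.lower_bound} > ub {self.upper_bound}"
            )
        if not self.stoichiometry and not self.is_exchange:
            raise ValueError(f"reaction {self.id!r}: empty stoichiometry")
        if not self.subsystem:
            self.subsystem = "unassigned"

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes()


class MetabolicModel:
    """A genome-scale (or toy) metabolic model.

    Parameters
    ----------
    metabolites, reactions
        Network content; ids must be unique within each class.
    genes
        Registered gene ids.  Genes referenced by GPRs but not listed are
        auto-registered with a warning recorded in :attr:`warnings`.
    objective_reaction
        Default objective for FBA (e.g. a lipid-droplet sink).
    """

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        genes: list[str] | None = None,
        objective_reaction: str | None = None,
        id: str = "model",
    ):
        self.id = id
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.genes = list(genes) if genes else []
        self.objective_reaction = objective_reaction
        self.warnings: list[str] = []
        self._validate()

    # -- construction / validation -------------------------------------
    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ValueError(f"duplicate metabolite ids: {dup}")
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ValueError(f"duplicate reaction ids: {dup}")
        met_set = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - met_set
            if missing:
                raise ValueError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
        gene_set = set(self.genes)
        for r in self.reactions:
            for g in sorted(r.genes):
                if g not in gene_set:
                    self.warnings.append(
                        f"gene {g!r} from GPR of {r.id!r} auto-registered"
                    )
                    gene_set.add(g)
                    self.genes.append(g)
        if self.objective_reaction is not None and self.objective_reaction not in set(
            rxn_ids
        ):
            raise ValueError(f"objective reaction {self.objective_reaction!r} not in model")
        self._met_index = {m: i for i, m in enumerate(met_ids)}
        self._rxn_index = {r: i for i, r in enumerate(rxn_ids)}

    # -- lookups --------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    # -- matrices -------------------------------------------------------
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S (metabolites x reactions), sparse CSR."""
        rows, cols, data = [], [], []
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                rows.append(self._met_index[met])
                cols.append(j)
                data.append(float(coef))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    def subsystems(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.subsystem)
        return list(seen)

    # -- editing --------------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def subset(self, reaction_ids: set[str] | list[str], id: str | None = None) -> "MetabolicModel":
        """New model restricted to ``reaction_ids``; orphan metabolites dropped."""
        keep = set(reaction_ids)
        missing = keep - set(self._rxn_index)
        if missing:
            raise KeyError(f"reactions not in model: {sorted(missing)}")
        rxns = [copy.deepcopy(r) for r in self.reactions if r.id in keep]
        used_mets = set()
        for r in rxns:
            used_mets |= set(r.stoichiometry)
        mets = [copy.deepcopy(m) for m in self.metabolites if m.id in used_mets]
        genes = sorted(set().union(*(r.genes for r in rxns)) if rxns else set())
        obj = self.objective_reaction if self.objective_reaction in keep else None
        return MetabolicModel(mets, rxns, genes, obj, id=id or self.id)

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id}: {len(self.genes)} genes, "
            f"{len(self.metabolites)} metabolites, {len(self.reactions)} reactions>"
        )


class FluxVector(dict):
    """Map reaction id -> flux (mmol/gDW/h), with the objective attached."""

    def __init__(self, data: dict[str, float], objective_value: float | None = None):
        super().__init__(data)
        self.objective_value = objective_value

    def to_array(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self[r] for r in model.reaction_ids], dtype=float)
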