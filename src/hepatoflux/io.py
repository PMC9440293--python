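"""Model and table I/O.

Two model formats are supported: SBML L3 FBC (read/written through
cobrapy, with subsystems taken from the groups package falling back to
reaction notes) and a native JSON dialect that round-trips every field of
:class:`~hepatoflux.model.MetabolicModel` exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .gpr import parse_gpr
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "read_model",
    "write_model",
    "read_expression_tsv",
    "read_sample_metadata",
]


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "objective_reaction": model.objective_reaction,
        "genes": list(model.genes),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "gpr": r.gpr.to_string(),
                "is_exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
    }


def _model_from_dict(d: dict) -> MetabolicModel:
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            formula=m.get("formula"),
        )
        for m in d["metabolites"]
    ]
    rxns = [
        Reaction(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            subsystem=r.get("subsystem", "unassigned"),
            gpr=parse_gpr(r.get("gpr", "")),
            is_exchange=bool(r.get("is_exchange", False)),
        )
        for r in d["reactions"]
    ]
    return MetabolicModel(
        mets, rxns, d.get("genes", []), d.get("objective_reaction"), id=d.get("id", "model")
    )


# ---------------------------------------------------------------------------
# SBML through cobrapy
# ---------------------------------------------------------------------------

def _model_from_cobra(cm) -> MetabolicModel:
    mets = [
        Metabolite(m.id, m.name or "", m.compartment or "c", m.formula)
        for m in cm.metabolites
    ]
    # subsystem: groups package first, then the reaction attribute/notes
    sub_by_rxn: dict[str, str] = {}
    for grp in getattr(cm, "groups", []):
        for member in grp.members:
            sub_by_rxn.setdefault(member.id, grp.name or grp.id)
    rxns = []
    for r in cm.reactions:
        sub = sub_by_rxn.get(r.id) or getattr(r, "subsystem", "") or \
            (r.notes.get("SUBSYSTEM") if isinstance(r.notes, dict) else "") or "unassigned"
        rxns.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                subsystem=sub,
                gpr=parse_gpr(r.gene_reaction_rule),
                is_exchange=bool(r.boundary),
            )
        )
    genes = [g.id for g in cm.genes]
    obj = None
    try:
        obj_rxns = [r.id for r in cm.reactions if r.objective_coefficient]
        if len(obj_rxns) == 1:
            obj = obj_rxns[0]
    except Exception:
        pass
    return MetabolicModel(mets, rxns, genes, obj, id=cm.id or "model")


def _model_to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    comps = {m.compartment for m in model.metabolites}
    cm.compartments = {c: c for c in comps}
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment,
                                formula=m.formula)
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, lower_bound=r.lower_bound,
                            upper_bound=r.upper_bound)
        crxns.append(cr)
    cm.add_reactions(crxns)
    groups: dict[str, list] = {}
    for r, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[k]: v for k, v in r.stoichiometry.items()})
        cr.gene_reaction_rule = r.gpr.to_string()
        groups.setdefault(r.subsystem, []).append(cr)
    for name, members in groups.items():
        grp = cobra.core.Group(name.replace(" ", "_"), name=name, members=members)
        cm.add_groups([grp])
    if model.objective_reaction:
        cm.objective = model.objective_reaction
    return cm


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_model(path: str | Path) -> MetabolicModel:
    """Read a model from SBML (``.xml``/``.sbml``) or the JSON dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return _model_from_dict(json.load(fh))
    from cobra.io import read_sbml_model

    return _model_from_cobra(read_sbml_model(str(path)))


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model to SBML or the JSON dialect (chosen by suffix)."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1)
        return
    from cobra.io import write_sbml_model

    write_sbml_model(_model_to_cobra(model), str(path))


def serialize_model(model: MetabolicModel) -> str:
    """Canonical JSON string of a model (used for bit-identity checks)."""
    return json.dumps(_model_to_dict(model), sort_keys=True)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression table; first column = gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("expression values must be non-negative")
    return df


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata table; first column = sample ids, must contain 'group'."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "group" not in df.columns:
        raise ValueError("sample metadata must have a 'group' column")
    return df
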