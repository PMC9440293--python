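"""Random sampling of the feasible flux space and subsystem aggregation.

The sampler is the non-uniform random-objective method: each sample draws
an objective vector c with i.i.d. components uniform on [-1, 1] over the
eligible (non-exchange, by default) reactions and stores the optimal
vertex of max c'v over {S v = 0, lb <= v <= ub}.  Samples therefore lie on
the boundary of the flux polytope; the method needs no metabolic
objective and is fully seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FLUX_TOL, InfeasibleModelError
from .lp import solve_lp
from .model import MetabolicModel

__all__ = ["FluxSampleMatrix", "random_sample", "subsystem_flux"]

#: cap applied to infinite bounds before sampling (mmol/gDW/h)
BOUND_CAP = 1000.0


@dataclass
class FluxSampleMatrix:
    """samples x reactions flux matrix with its provenance."""

    values: pd.DataFrame  # index: sample number, columns: reaction ids
    model_id: str
    seed: int
    n_samples: int

    @property
    def reactions(self) -> list[str]:
        return list(self.values.columns)


def random_sample(
    model: MetabolicModel,
    n: int = 1000,
    seed: int = 0,
    include_exchanges: bool = False,
) -> FluxSampleMatrix:
    """Draw ``n`` random-objective vertex samples from the flux polytope."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    capped = ~np.isfinite(lb) | ~np.isfinite(ub)
    if capped.any():
        warnings.warn(f"capping {int(capped.sum())} infinite bounds at ±{BOUND_CAP}")
    lb = np.clip(lb, -BOUND_CAP, BOUND_CAP)
    ub = np.clip(ub, -BOUND_CAP, BOUND_CAP)
    nrxn = len(model.reactions)
    eligible = np.array(
        [include_exchanges or not r.is_exchange for r in model.reactions]
    )
    # feasibility check up front
    chk = solve_lp(np.zeros(nrxn), A_eq=S, b_eq=np.zeros(S.shape[0]), lb=lb, ub=ub,
                   sense="min")
    if chk.status == "infeasible":
        raise InfeasibleModelError(f"model {model.id!r} is infeasible")
    rng = np.random.default_rng(seed)
    rows = np.empty((n, nrxn))
    b0 = np.zeros(S.shape[0])
    for s in range(n):
        c = np.zeros(nrxn)
        c[eligible] = rng.uniform(-1.0, 1.0, int(eligible.sum()))
        res = solve_lp(c, A_eq=S, b_eq=b0, lb=lb, ub=ub, sense="max")
        if not res.ok:  # pragma: no cover - cannot happen on a bounded region
            raise RuntimeError(f"sampling LP failed: {res.message}")
        rows[s] = res.x
    df = pd.DataFrame(rows, columns=model.reaction_ids)
    return FluxSampleMatrix(df, model_id=model.id, seed=seed, n_samples=n)


def subsystem_flux(
    samples: FluxSampleMatrix,
    model: MetabolicModel,
    measurable_threshold: float = FLUX_TOL,
    include_exchanges: bool = False,
) -> pd.DataFrame:
    """Aggregate sampled fluxes to subsystem level.

    Reactions whose |flux| never exceeds ``measurable_threshold`` across
    samples are dropped; the absolute values of the remaining fluxes are
    averaged within each subsystem, per sample.  Returns a subsystems x
    samples table; subsystems left without measurable reactions are
    dropped with a warning.
    """
    df = samples.values
    missing = set(df.columns) ^ set(model.reaction_ids)
    if missing:
        raise ValueError(f"samples and model disagree on reactions: {sorted(missing)[:5]}")
    measurable = (df.abs() > measurable_threshold).any(axis=0)
    sub_of = {
        r.id: r.subsystem
        for r in model.reactions
        if include_exchanges or not r.is_exchange
    }
    out = {}
    for sub in model.subsystems():
        members = [
            rid for rid, s in sub_of.items() if s == sub and measurable.get(rid, False)
        ]
        if sub not in set(sub_of.values()):
            continue
        if not members:
            warnings.warn(f"subsystem {sub!r} has no measurable reactions; dropped")
            continue
        out[sub] = df[members].abs().mean(axis=1)
    cols = [f"s{i}" for i in range(df.shape[0])]
    if not out:
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(out).T
    table.columns = cols
    return table
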