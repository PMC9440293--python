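"""Flux balance analysis, flux variability analysis and FASTCC consistency.

FBA solves ``optimize v_obj s.t. S v = 0, lb <= v <= ub``.  FVA computes the
per-reaction flux range over the same polytope.  FASTCC extracts the
flux-consistent subnetwork — the reactions that can carry a flux of at
least ``flux_tolerance`` in some steady state — using the LP-7/LP-3
iterative support-maximization scheme rather than per-reaction FVA.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .lp import LPResult, solve_lp
from .model import FluxVector, MetabolicModel

__all__ = ["fba", "fva", "fastcc", "InfeasibleModelError"]

#: default measurable-flux cutoff (mmol/gDW/h)
FLUX_TOL = 1e-6


class InfeasibleModelError(RuntimeError):
    """The model's feasible region is empty."""


def fba(
    model: MetabolicModel,
    objective: str | None = None,
    sense: str = "max",
) -> FluxVector:
    """Flux balance analysis.

    Returns the optimal :class:`FluxVector` (with ``objective_value`` set).
    Raises :class:`InfeasibleModelError` on an infeasible model; an
    unbounded objective raises ``ValueError``.
    """
    objective = objective or model.objective_reaction
    if objective is None:
        raise ValueError("no objective reaction given and model has no default")
    if objective not in model:
        raise ValueError(f"objective reaction {objective!r} not in model")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    c = np.zeros(len(model.reactions))
    c[model.reaction_index(objective)] = 1.0
    res = solve_lp(c, A_eq=S, b_eq=np.zeros(S.shape[0]), lb=lb, ub=ub, sense=sense)
    if res.status == "infeasible":
        raise InfeasibleModelError(f"model {model.id!r} is infeasible")
    if res.status == "unbounded":
        raise ValueError(f"objective {objective!r} is unbounded in {model.id!r}")
    if not res.ok:
        raise RuntimeError(f"LP solver failure: {res.message}")
    return FluxVector(
        dict(zip(model.reaction_ids, res.x)), objective_value=res.objective
    )


def fva(
    model: MetabolicModel,
    reactions: list[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis: (min, max) flux per reaction."""
    rxns = reactions if reactions is not None else model.reaction_ids
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    n = len(model.reactions)
    b0 = np.zeros(S.shape[0])
    out: dict[str, tuple[float, float]] = {}
    for rid in rxns:
        c = np.zeros(n)
        c[model.reaction_index(rid)] = 1.0
        lo = solve_lp(c, A_eq=S, b_eq=b0, lb=lb, ub=ub, sense="min")
        hi = solve_lp(c, A_eq=S, b_eq=b0, lb=lb, ub=ub, sense="max")
        if lo.status == "infeasible" or hi.status == "infeasible":
            raise InfeasibleModelError(f"model {model.id!r} is infeasible")
        out[rid] = (lo.objective, hi.objective)
    return out


# ---------------------------------------------------------------------------
# FASTCC
# ---------------------------------------------------------------------------

def _lp7(
    S: sparse.spmatrix,
    lb: np.ndarray,
    ub: np.ndarray,
    J: np.ndarray,
    eps: float,
) -> LPResult:
    """LP-7: maximize the number of reactions in J carrying flux >= eps.

    Auxiliary variables z_j in [0, eps] with z_j <= v_j; maximize sum z.
    """
    n = S.shape[1]
    k = J.size
    # variables: [v (n), z (k)]
    c = np.concatenate([np.zeros(n), np.ones(k)])
    A_eq = sparse.hstack([S, sparse.csr_matrix((S.shape[0], k))], format="csr")
    # z_j - v_j <= 0
    rows = np.arange(k)
    A_ub = sparse.hstack(
        [
            sparse.csr_matrix((-np.ones(k), (rows, J)), shape=(k, n)),
            sparse.identity(k, format="csr"),
        ],
        format="csr",
    )
    lo = np.concatenate([lb, np.zeros(k)])
    hi = np.concatenate([ub, np.full(k, eps)])
    return solve_lp(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=np.zeros(k),
        lb=lo,
        ub=hi,
        sense="max",
    )


def fastcc(model: MetabolicModel, flux_tolerance: float = FLUX_TOL) -> set[str]:
    """Flux-consistent reaction set via the FASTCC LP-7/LP-3 scheme.

    Returns the ids of reactions that can carry ``|v| >= flux_tolerance``
    in some feasible steady state.  Reversible reactions that fail in the
    forward direction are retried with their column sign flipped.
    """
    S = model.stoichiometric_matrix().tocsc()
    lb, ub = model.bounds()
    n = len(model.reactions)
    rids = np.array(model.reaction_ids)
    # LP numerics: support maximization with an eps at the raw 1e-6
    # tolerance sits at solver noise level; the flux cone is scale-free
    # away from finite bounds, so a larger internal eps finds the same
    # support.  Validated against the FVA oracle in the test suite.
    eps = max(flux_tolerance, 1e-4)
    supp_tol = 0.9 * flux_tolerance

    irreversible = lb >= 0
    consistent = np.zeros(n, dtype=bool)

    def support(v: np.ndarray) -> np.ndarray:
        return np.abs(v[:n]) >= supp_tol

    # flips[i] = True means reaction i currently has its column negated
    flips = np.zeros(n, dtype=bool)

    def current() -> tuple[sparse.spmatrix, np.ndarray, np.ndarray]:
        if not flips.any():
            return S, lb, ub
        sgn = np.where(flips, -1.0, 1.0)
        D = sparse.diags(sgn)
        Sf = S @ D
        lbf = np.where(flips, -ub, lb)
        ubf = np.where(flips, -lb, ub)
        return Sf, lbf, ubf

    # phase 1: all irreversible reactions at once
    J = np.flatnonzero(irreversible)
    if J.size:
        res = _lp7(S, lb, ub, J, eps)
        if res.status == "infeasible":
            raise InfeasibleModelError(f"model {model.id!r} is infeasible")
        consistent |= support(res.x)
    blocked_irrev = irreversible & ~consistent

    todo = [i for i in range(n) if not consistent[i] and not blocked_irrev[i]]

    J = np.array(todo, dtype=int)
    flipped = False
    singleton = False
    while J.size:
        Ji = J[:1] if singleton else J
        Sf, lbf, ubf = current()
        res = _lp7(Sf, lbf, ubf, Ji, eps)
        if not res.ok:  # pragma: no cover - solver failure path
            raise RuntimeError(f"FASTCC LP failure: {res.message}")
        consistent |= support(res.x)
        if consistent[J].any():
            J = J[~consistent[J]]
            flipped = False
            singleton = False
        else:
            rev_in_ji = np.array([not irreversible[i] for i in Ji])
            if flipped or not rev_in_ji.any():
                flipped = False
                if singleton:
                    J = J[1:]  # blocked
                else:
                    singleton = True
            else:
                flips[Ji[rev_in_ji]] = ~flips[Ji[rev_in_ji]]
                flipped = True
    return set(rids[consistent])
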