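"""Independent reference implementations used for validation.

These deliberately avoid the algorithms they check: the iMAT reference
enumerates indicator assignments and tests each with a plain feasibility
LP (no MILP); the consistency reference runs per-reaction FVA (no LP-7
support maximization).  They are exponential/quadratic and only usable on
toy problems.
"""

from __future__ import annotations

import itertools

import numpy as np

from .core import FLUX_TOL, fva
from .expression import Category
from .lp import solve_lp
from .model import MetabolicModel

__all__ = ["imat_bruteforce", "fva_consistent_set"]


def imat_bruteforce(
    model: MetabolicModel,
    categories: dict[str, Category],
    epsilon: float = 1.0,
) -> int:
    """Maximum iMAT objective by exhaustive enumeration.

    Every assignment of HIGH reactions to {forward-active, reverse-active,
    unsatisfied} and LOW reactions to {silenced, unsatisfied} is checked
    with a feasibility LP that pins the committed reactions
    (v >= eps / v <= -eps / v = 0); the best feasible satisfaction count
    is returned.  Assignments are visited in decreasing count order so the
    search can stop at the first feasible one.
    """
    high = [r.id for r in model.reactions if categories.get(r.id) == Category.HIGH]
    low = [
        r.id
        for r in model.reactions
        if categories.get(r.id) == Category.LOW and not r.is_exchange
    ]
    S = model.stoichiometric_matrix()
    lb0, ub0 = model.bounds()
    n = len(model.reactions)
    b0 = np.zeros(S.shape[0])

    def feasible(hi_states: tuple[int, ...], lo_states: tuple[int, ...]) -> bool:
        lb, ub = lb0.copy(), ub0.copy()
        for rid, st in zip(high, hi_states):
            i = model.reaction_index(rid)
            if st == 1:
                lb[i] = max(lb[i], epsilon)
            elif st == -1:
                ub[i] = min(ub[i], -epsilon)
            if lb[i] > ub[i]:
                return False
        for rid, st in zip(low, lo_states):
            i = model.reaction_index(rid)
            if st == 1:
                if lb[i] > 0 or ub[i] < 0:
                    return False
                lb[i] = ub[i] = 0.0
        res = solve_lp(np.zeros(n), A_eq=S, b_eq=b0, lb=lb, ub=ub, sense="min")
        return res.ok

    candidates = []
    for hi in itertools.product((1, -1, 0), repeat=len(high)):
        for lo in itertools.product((1, 0), repeat=len(low)):
            count = sum(s != 0 for s in hi) + sum(lo)
            candidates.append((count, hi, lo))
    candidates.sort(key=lambda c: -c[0])
    for count, hi, lo in candidates:
        if feasible(hi, lo):
            return count
    return 0


def fva_consistent_set(
    model: MetabolicModel, flux_tolerance: float = FLUX_TOL
) -> set[str]:
    """Flux-consistent reactions by per-reaction FVA (blocked-reaction oracle)."""
    env = fva(model)
    return {
        rid
        for rid, (lo, hi) in env.items()
        if max(abs(lo), abs(hi)) >= flux_tolerance
    }
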