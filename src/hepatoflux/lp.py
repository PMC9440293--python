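"""Thin LP/MILP layer over scipy's HiGHS bindings.

All flux-balance problems in the package reduce to

    optimize c'x  s.t.  A_eq x = b_eq, A_ub x <= b_ub, lb <= x <= ub

solved with `scipy.optimize.linprog` (LP) or `scipy.optimize.milp` (MILP).
Results are returned in a small container so callers can distinguish
optimal / infeasible / unbounded without exception gymnastics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, linprog, milp

__all__ = ["LPResult", "solve_lp", "solve_milp"]

#: primal feasibility tolerance requested from HiGHS
FEASIBILITY_TOL = 1e-9


@dataclass
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    x: np.ndarray | None
    objective: float | None
    message: str = ""
    mip_gap: float | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_lp(
    c: np.ndarray,
    A_eq: sparse.spmatrix | None = None,
    b_eq: np.ndarray | None = None,
    A_ub: sparse.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
    sense: str = "max",
) -> LPResult:
    """Solve an LP; ``sense`` is ``"max"`` or ``"min"``."""
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    bounds = list(
        zip(
            (np.full(c.size, -np.inf) if lb is None else lb),
            (np.full(c.size, np.inf) if ub is None else ub),
        )
    )
    res = linprog(
        sign * c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return LPResult(status, None, None, res.message)
    return LPResult("optimal", res.x, sign * res.fun, res.message)


def solve_milp(
    c: np.ndarray,
    integrality: np.ndarray,
    constraints: list[LinearConstraint],
    lb: np.ndarray,
    ub: np.ndarray,
    sense: str = "max",
    mip_gap: float = 1e-4,
    time_limit: float | None = None,
) -> LPResult:
    """Solve a MILP; ``integrality`` is 0 (continuous) / 1 (integer) per var."""
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    from scipy.optimize import Bounds

    options: dict = {"mip_rel_gap": mip_gap}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        sign * c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options=options,
    )
    if res.status == 0 or (res.status == 1 and res.x is not None):
        # 0 = optimal; 1 = iteration/time limit with incumbent
        gap = getattr(res, "mip_gap", None)
        return LPResult("optimal", res.x, sign * res.fun, res.message, mip_gap=gap)
    if res.status == 2:
        return LPResult("infeasible", None, None, res.message)
    if res.status == 3:
        return LPResult("unbounded", None, None, res.message)
    return LPResult("error", None, None, res.message)
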