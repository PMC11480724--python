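"""Thin wrapper around scipy's HiGHS interface used by every LP in the toolkit.

All linear programs in comgem (FBA, FVA, SteadyCom, lexicographic and
fixed-composition solves) are assembled as sparse matrices and passed through
:func:`solve_lp`, so solver options and status mapping live in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {0: OPTIMAL, 1: "iteration_limit", 2: INFEASIBLE, 3: UNBOUNDED, 4: "numerical"}

# HiGHS feasibility tolerance; tighter than default so chained lexicographic
# solves on small models do not accumulate drift.
FEAS_TOL = 1e-9


@dataclass
class LPResult:
    status: str
    x: np.ndarray | None
    objective: float | None  # value of the *maximized* objective


def solve_lp(
    c,
    A_eq=None,
    b_eq=None,
    A_ub=None,
    b_ub=None,
    bounds=None,
    sense: str = "max",
) -> LPResult:
    """Solve ``max/min c.x`` s.t. ``A_eq x = b_eq``, ``A_ub x <= b_ub``, bounds.

    ``bounds`` is a sequence of ``(lb, ub)`` pairs; ``None`` entries mean
    unbounded on that side. Returns the objective on the requested sense.
    """
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    if A_eq is not None:
        A_eq = sp.csr_matrix(A_eq)
    if A_ub is not None:
        A_ub = sp.csr_matrix(A_ub)
    res = linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": FEAS_TOL,
            "dual_feasibility_tolerance": FEAS_TOL,
        },
    )
    status = _STATUS.get(res.status, "failed")
    if status != OPTIMAL:
        return LPResult(status=status, x=None, objective=None)
    return LPResult(status=OPTIMAL, x=res.x, objective=sign * res.fun)
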