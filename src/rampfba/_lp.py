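"""Thin wrapper around scipy's HiGHS linear-programming backend.

Every LP in the package goes through :func:`solve_lp` so that status mapping
and solver options live in one place.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

#: Canonical solver statuses used across the package.
OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
NUMERIC_FAILURE = "numeric_failure"

_STATUS_MAP = {0: OPTIMAL, 1: NUMERIC_FAILURE, 2: INFEASIBLE, 3: UNBOUNDED, 4: NUMERIC_FAILURE}


def solve_lp(
    c: np.ndarray,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
    A_eq: Optional[np.ndarray] = None,
    b_eq: Optional[np.ndarray] = None,
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
) -> Tuple[str, Optional[np.ndarray], Optional[float]]:
    """Minimize ``c @ x`` subject to linear constraints; return (status, x, fun)."""
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    status = _STATUS_MAP.get(res.status, NUMERIC_FAILURE)
    if status == OPTIMAL:
        return status, np.asarray(res.x, dtype=float), float(res.fun)
    return status, None, None
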