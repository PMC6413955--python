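"""Thin LP layer over scipy's HiGHS interface.

All optimizations in the package go through :func:`maximize`: maximize
``c . v`` subject to ``S v = 0`` and ``lb <= v <= ub``.  HiGHS is
deterministic for a fixed input, which keeps flux vectors reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = ["LPResult", "maximize"]

#: equality feasibility tolerance used when verifying solutions
FEASIBILITY_TOL = 1e-6


@dataclass(frozen=True)
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: Optional[float]
    x: Optional[np.ndarray]


def maximize(S: sp.spmatrix, lb: np.ndarray, ub: np.ndarray, c: np.ndarray) -> LPResult:
    """Maximize ``c . v`` s.t. ``S v = 0``, ``lb <= v <= ub``."""
    res = linprog(
        c=-np.asarray(c, dtype=float),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 0:
        return LPResult("optimal", -float(res.fun), np.asarray(res.x))
    if res.status == 2:
        return LPResult("infeasible", None, None)
    if res.status == 3:
        return LPResult("unbounded", None, None)
    raise RuntimeError(f"LP solver failure: {res.message}")


def column_objective(n_cols: int, index: int, sense: float = 1.0) -> np.ndarray:
    c = np.zeros(n_cols)
    c[index] = sense
    return c
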