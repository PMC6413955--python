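"""Project activity scores onto per-cell flux bounds.

The reachable capacity of each reaction is measured first (flux variability
with no optimality requirement, under medium constraints only); the per-cell
upper bound is then the epsilon floor plus the capacity share proportional to
the cell's normalized activity score:
``U = eps + (F - eps) * share``.  Irreversible reactions keep a zero lower
bound; reversible reactions get ``L = -U``, since expression evidence does
not distinguish the two directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._lp import column_objective, maximize
from .population import PopulationModel
from .ras import RASMatrix

__all__ = ["CapacityTable", "compute_flux_capacities", "apply_ras_bounds", "EPSILON_DEFAULT"]

log = logging.getLogger(__name__)

EPSILON_DEFAULT = 1e-3

#: capacities below this magnitude are treated as exactly zero
_CAPACITY_FLOOR = 1e-9


@dataclass(frozen=True)
class CapacityTable:
    """Per template reaction: FVA extremes and capacity F = max(|F_f|, |F_b|).

    Cells are identical before score integration, so capacities are computed
    on one representative cell's columns and hold for every cell.
    """

    f_forward: pd.Series  # reaction id -> FVA max
    f_backward: pd.Series  # reaction id -> FVA min
    capacity: pd.Series  # reaction id -> F

    def __post_init__(self) -> None:
        if (self.capacity < 0).any():
            raise ValueError("capacities must be non-negative")


def compute_flux_capacities(
    model: PopulationModel, reactions: Optional[Sequence[str]] = None
) -> CapacityTable:
    """Flux variability (0% optimality) of template reactions on *model*.

    *model* must carry only type-1 (medium) constraints.  By default every
    template reaction (internal reactions and exchanges-turned-cooperation)
    is measured; pass *reactions* to restrict.  Raises if the medium alone is
    infeasible.
    """
    if reactions is None:
        reactions = [r.id for r in model.template.reactions] + [
            e.id for e in model.template.exchanges
        ]
    n = len(model.columns)

    probe = maximize(model.S, model.lb, model.ub, np.zeros(n))
    if probe.status != "optimal":
        raise ValueError(f"population model infeasible under medium constraints ({probe.status})")

    internal_ids = {r.id for r in model.template.reactions}
    species_of = {e.id: next(iter(e.stoichiometry)) for e in model.template.exchanges}
    fwd: Dict[str, float] = {}
    bwd: Dict[str, float] = {}
    for rid in reactions:
        if rid in internal_ids:
            col = model.column("internal", 1, rid)
        else:
            col = model.column("cooperation", 1, species_of[rid])
        hi = maximize(model.S, model.lb, model.ub, column_objective(n, col, +1.0))
        lo = maximize(model.S, model.lb, model.ub, column_objective(n, col, -1.0))
        if hi.status != "optimal" or lo.status != "optimal":
            raise ValueError(f"FVA failed for reaction {rid!r}")
        fwd[rid] = hi.objective_value
        bwd[rid] = -lo.objective_value

    f_forward = pd.Series(fwd)
    f_backward = pd.Series(bwd)
    capacity = np.maximum(f_forward.abs(), f_backward.abs())
    capacity[capacity < _CAPACITY_FLOOR] = 0.0
    return CapacityTable(f_forward=f_forward, f_backward=f_backward, capacity=capacity)


def apply_ras_bounds(
    model: PopulationModel,
    caps: CapacityTable,
    ras: RASMatrix,
    epsilon: float = EPSILON_DEFAULT,
) -> PopulationModel:
    """Return a copy of *model* with type-2 (per-cell) bounds installed.

    For each scored reaction j and cell c:
    ``U_j^c = eps + (F_j - eps) * share_j^c`` with ``share`` the normalized
    score (zero-total rows give every cell the plain epsilon floor);
    ``L_j^c = 0`` for irreversible reactions, ``-U_j^c`` otherwise.
    Exchange-derived scores bound the cooperation columns.  Unscored
    reactions keep their capacity bounds.  If ``eps`` exceeds a capacity the
    bound is clamped to ``eps`` (warning).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if ras.normalized is None:
        raise ValueError("RAS matrix must be normalized first (normalize_ras)")
    if model.n_cells != ras.normalized.shape[1]:
        raise ValueError(
            f"model has {model.n_cells} cells but RAS has {ras.normalized.shape[1]}"
        )

    out = model.copy()
    internal_ids = {r.id for r in model.template.reactions}
    reversible = {r.id: r.reversible for r in model.template.reactions}
    species_of = {e.id: next(iter(e.stoichiometry)) for e in model.template.exchanges}
    # cooperation columns are reversible by construction
    clamped = []

    for rid in caps.capacity.index:
        F = float(caps.capacity[rid])
        scored = rid in ras.normalized.index
        shares = ras.normalized.loc[rid].to_numpy() if scored else None
        is_internal = rid in internal_ids
        rev = reversible[rid] if is_internal else True
        for c in range(1, model.n_cells + 1):
            col = (
                out.column("internal", c, rid)
                if is_internal
                else out.column("cooperation", c, species_of[rid])
            )
            if scored:
                U = epsilon + (F - epsilon) * float(shares[c - 1])
                if U < epsilon:
                    clamped.append(rid)
                    U = epsilon
            else:
                U = F
            out.ub[col] = U
            out.lb[col] = -U if rev else 0.0
    if clamped:
        log.warning(
            "apply_ras_bounds: epsilon %g exceeded capacity for %d reaction bounds; clamped",
            epsilon,
            len(set(clamped)),
        )
    return out
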