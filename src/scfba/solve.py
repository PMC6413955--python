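"""Population optimization and in-silico experiments.

Provides the LP optimization of the population model (biomass or ATP
objective), per-cell biomass variability at the population optimum,
single-gene deletion growth ratios, and the cooperation-knockout ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._lp import LPResult, column_objective, maximize
from .bounds import CapacityTable, apply_ras_bounds
from .expression import ExpressionData
from .network import TemplateNetwork, disabled_reactions
from .population import PopulationModel, add_atp_demand
from .ras import compute_ras_matrix, normalize_ras

__all__ = [
    "FluxSolution",
    "DeletionReport",
    "RasContext",
    "optimize_population",
    "per_cell_biomass_span",
    "single_gene_deletion",
    "cooperation_knockout_ratio",
]

log = logging.getLogger(__name__)

#: relative slack when pinning the objective at its optimum for FVA
_OPT_PIN_TOL = 1e-9


@dataclass(frozen=True)
class FluxSolution:
    """One optimal flux distribution of the population model."""

    status: str
    objective_value: Optional[float]
    v: Optional[np.ndarray]

    def flux_frame(self, model: PopulationModel) -> pd.DataFrame:
        """Long-form table: column id, kind, cell, reference, flux."""
        if self.v is None:
            raise ValueError(f"no flux vector (status: {self.status})")
        records = [
            {"column": meta.name, "kind": meta.kind, "cell": meta.cell, "ref": meta.ref,
             "flux": float(val)}
            for meta, val in zip(model.columns, self.v)
        ]
        return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class RasContext:
    """Everything needed to rebuild type-2 bounds after a gene knockout."""

    expression: ExpressionData
    capacities: CapacityTable
    epsilon: float


@dataclass(frozen=True)
class DeletionReport:
    """Growth ratios (knockout optimum / baseline optimum) per gene."""

    gr_ratio: pd.Series  # gene -> ratio in [0, 1]
    disabled: Dict[str, Set[str]]  # gene -> reactions removed
    baseline: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grRatio": self.gr_ratio,
                "disabled_reactions": [
                    ";".join(sorted(self.disabled[g])) for g in self.gr_ratio.index
                ],
            }
        )


def _objective_model(model: PopulationModel, objective: str, atp_species: Optional[str]):
    if objective == "biomass":
        return model
    if objective == "atp":
        if atp_species is None:
            raise ValueError("atp objective requires atp_species")
        return add_atp_demand(model, atp_species)
    raise ValueError(f"unknown objective {objective!r}")


def optimize_population(
    model: PopulationModel,
    objective: str = "biomass",
    atp_species: Optional[str] = None,
) -> FluxSolution:
    """Maximize the population objective (total biomass, or total ATP demand)."""
    work = _objective_model(model, objective, atp_species)
    c = np.zeros(len(work.columns))
    c[work.objective_cols] = 1.0
    res = maximize(work.S, work.lb, work.ub, c)
    if res.status != "optimal":
        return FluxSolution(res.status, None, None)
    return FluxSolution("optimal", res.objective_value, res.x)


def per_cell_biomass_span(
    model: PopulationModel, solution: Optional[FluxSolution] = None
) -> pd.DataFrame:
    """FVA of each cell's biomass flux with the total pinned at its optimum.

    Returns a frame indexed by cell with columns ``min``, ``max``, ``total``
    and the fractional spans ``min_frac`` / ``max_frac``.
    """
    if solution is None:
        solution = optimize_population(model)
    if solution.status != "optimal":
        raise ValueError(f"population model not solvable ({solution.status})")
    total = solution.objective_value

    pinned = model.copy()
    for j in pinned.objective_cols:
        pinned.lb[j] = max(pinned.lb[j], total - _OPT_PIN_TOL * max(1.0, abs(total)))

    n = len(pinned.columns)
    rows = []
    for cell, col in zip(range(1, model.n_cells + 1), model.biomass_columns()):
        hi = maximize(pinned.S, pinned.lb, pinned.ub, column_objective(n, col, +1.0))
        lo = maximize(pinned.S, pinned.lb, pinned.ub, column_objective(n, col, -1.0))
        if hi.status != "optimal" or lo.status != "optimal":
            raise RuntimeError(f"biomass FVA failed for cell {cell}")
        vmin, vmax = -lo.objective_value, hi.objective_value
        rows.append(
            {
                "cell": cell,
                "min": vmin,
                "max": vmax,
                "total": total,
                "min_frac": vmin / total if total > 0 else np.nan,
                "max_frac": vmax / total if total > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def _knockout_model(
    model: PopulationModel,
    net: TemplateNetwork,
    gene: str,
    ras_context: Optional[RasContext],
) -> Tuple[PopulationModel, Set[str]]:
    dead = disabled_reactions(net, {gene})
    if ras_context is not None:
        # re-derive type-2 bounds with the gene silenced, so that reactions
        # surviving on an unexpressed isoform fall to the epsilon floor
        expr = ras_context.expression
        values = expr.values.copy()
        if gene in values.index:
            values.loc[gene, :] = 0.0
        silenced = ExpressionData(values=values, bulk=expr.bulk, gene_status=expr.gene_status)
        ras = normalize_ras(compute_ras_matrix(net, silenced))
        work = apply_ras_bounds(model, ras_context.capacities, ras, ras_context.epsilon)
    else:
        work = model.copy()

    internal_ids = {r.id for r in net.reactions}
    species_of = {e.id: next(iter(e.stoichiometry)) for e in net.exchanges}
    for rid in dead:
        for c in range(1, work.n_cells + 1):
            if rid in internal_ids:
                col = work.column("internal", c, rid)
            else:
                col = work.column("cooperation", c, species_of[rid])
            work.lb[col] = 0.0
            work.ub[col] = 0.0
    return work, dead


def single_gene_deletion(
    model: PopulationModel,
    net: TemplateNetwork,
    genes: Optional[Sequence[str]] = None,
    *,
    ras_context: Optional[RasContext] = None,
    objective: str = "biomass",
    atp_species: Optional[str] = None,
) -> DeletionReport:
    """Knock out each gene (in every cell at once) and record the growth ratio.

    Disabled reactions are those whose GPR becomes unsatisfiable; their
    columns are zero-bounded in all cells.  With *ras_context* given
    (score-constrained mode), per-cell bounds are additionally recomputed
    with the gene's transcript silenced, so deletions can bite through the
    score normalization even when an unexpressed isoform keeps the GPR true.
    """
    if genes is None:
        genes = sorted(net.genes)
    baseline = optimize_population(model, objective, atp_species)
    if baseline.status != "optimal" or baseline.objective_value is None:
        raise ValueError(f"baseline optimization failed ({baseline.status})")
    base = baseline.objective_value

    net_genes = net.genes
    ratios = {}
    disabled: Dict[str, Set[str]] = {}
    for gene in genes:
        if gene not in net_genes:
            ratios[gene] = 1.0  # gene absent from every GPR: nothing changes
            disabled[gene] = set()
            continue
        work, dead = _knockout_model(model, net, gene, ras_context)
        disabled[gene] = dead
        if not dead and ras_context is None:
            ratios[gene] = 1.0  # nothing disabled, bounds untouched
            continue
        res = optimize_population(work, objective, atp_species)
        opt = res.objective_value if res.status == "optimal" else 0.0
        ratio = opt / base if base > 0 else np.nan
        ratios[gene] = float(min(max(ratio, 0.0), 1.0))
    return DeletionReport(
        gr_ratio=pd.Series(ratios, name="grRatio"), disabled=disabled, baseline=base
    )


def cooperation_knockout_ratio(
    model: PopulationModel,
    objective: str = "biomass",
    species: Optional[Sequence[str]] = None,
    atp_species: Optional[str] = None,
) -> Optional[float]:
    """Optimum with cooperation blocked over optimum with cooperation open.

    Blocks the cooperation columns of the designated exchange species (by
    default the medium's TME-secretable set) in every cell — never the
    biomass pooling columns — and re-optimizes.  Returns ``None`` when the
    open optimum is zero (ratio undefined).
    """
    if species is None:
        if model.medium is None:
            raise ValueError("no medium applied; pass the species to block explicitly")
        species = sorted(model.medium.secretable_to_tme)
    species = [s for s in species if s != model.biomass_species]

    open_res = optimize_population(model, objective, atp_species)
    if open_res.status != "optimal":
        raise ValueError(f"open-model optimization failed ({open_res.status})")
    if not open_res.objective_value or open_res.objective_value <= 0:
        log.warning("cooperation_knockout_ratio: open optimum is zero; ratio undefined")
        return None

    blocked = model.copy()
    for s in species:
        for col in blocked.cooperation_columns(s):
            blocked.lb[col] = 0.0
            blocked.ub[col] = 0.0
    blocked_res = optimize_population(blocked, objective, atp_species)
    blocked_opt = blocked_res.objective_value if blocked_res.status == "optimal" else 0.0
    return float(blocked_opt / open_res.objective_value)


def cooperation_flux_ranges(
    model: PopulationModel, species: Sequence[str], solution: Optional[FluxSolution] = None
) -> pd.DataFrame:
    """FVA ranges of cooperation fluxes at the population optimum.

    Optimal cooperation fluxes are generally degenerate (one vertex among
    many); this reports the min/max range per (species, cell) instead of
    pretending uniqueness.
    """
    if solution is None:
        solution = optimize_population(model)
    if solution.status != "optimal":
        raise ValueError("model not solvable")
    total = solution.objective_value
    pinned = model.copy()
    for j in pinned.objective_cols:
        pinned.lb[j] = max(pinned.lb[j], total - _OPT_PIN_TOL * max(1.0, abs(total)))
    n = len(pinned.columns)
    rows = []
    for s in species:
        for cell, col in zip(range(1, model.n_cells + 1), model.cooperation_columns(s)):
            hi = maximize(pinned.S, pinned.lb, pinned.ub, column_objective(n, col, +1.0))
            lo = maximize(pinned.S, pinned.lb, pinned.ub, column_objective(n, col, -1.0))
            rows.append(
                {
                    "species": s,
                    "cell": cell,
                    "min": -lo.objective_value,
                    "max": hi.objective_value,
                    "at_optimum": float(solution.v[col]),
                }
            )
    return pd.DataFrame(rows)
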