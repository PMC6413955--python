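"""End-to-end orchestration: preprocess -> scores -> build -> bounds -> solve.

Three simulation modes share the plumbing:

* ``popFBA``  — population of identical cells, medium constraints only;
* ``bulkFBA`` — the single template network after deleting genes that are off
  in bulk and in every cell (no per-cell modulation);
* ``scFBA``   — population of cells with per-cell score-derived bounds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .bounds import CapacityTable, EPSILON_DEFAULT, apply_ras_bounds, compute_flux_capacities
from .expression import ExpressionData, filter_cells, reconcile_with_bulk
from .network import TemplateNetwork, delete_genes
from .population import MediumSpec, PopulationModel, apply_medium, build_population_model
from .ras import RASMatrix, compute_ras_matrix, normalize_ras
from .solve import FluxSolution, RasContext, optimize_population

__all__ = ["RunConfig", "ScfbaRun", "prepare_run", "run_pipeline", "epsilon_scan", "EPSILON_SCAN_VALUES"]

log = logging.getLogger(__name__)

MODES = ("popFBA", "bulkFBA", "scFBA")

#: epsilon sensitivity sweep values
EPSILON_SCAN_VALUES = (0.0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class RunConfig:
    """Reproducible configuration of one pipeline run."""

    mode: str = "scFBA"
    epsilon: float = EPSILON_DEFAULT
    objective: str = "biomass"
    atp_species: Optional[str] = None
    min_genes_detected: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ScfbaRun:
    """All artifacts of one prepared (and optionally solved) run."""

    config: RunConfig
    template: TemplateNetwork
    template_star: TemplateNetwork
    expression: ExpressionData
    g_off: Set[str]
    model: PopulationModel
    ras: Optional[RASMatrix] = None
    capacities: Optional[CapacityTable] = None
    solution: Optional[FluxSolution] = None

    @property
    def ras_context(self) -> Optional[RasContext]:
        if self.ras is None or self.capacities is None:
            return None
        return RasContext(
            expression=self.expression,
            capacities=self.capacities,
            epsilon=self.config.epsilon,
        )


def prepare_run(
    net: TemplateNetwork,
    data: ExpressionData,
    medium: MediumSpec,
    config: RunConfig,
) -> ScfbaRun:
    """Preprocess the data and assemble the constrained population model."""
    if config.min_genes_detected > 0:
        data = filter_cells(data, config.min_genes_detected)
    data, g_off = reconcile_with_bulk(data)
    overlap = set(data.values.index) & set(net.genes)
    if not overlap:
        raise ValueError("expression matrix and network GPRs share no genes")

    star = delete_genes(net, g_off)
    if config.mode == "popFBA":
        model = apply_medium(build_population_model(net, data.n_cells), medium)
        return ScfbaRun(config, net, star, data, g_off, model)
    if config.mode == "bulkFBA":
        model = apply_medium(build_population_model(star, 1), medium)
        return ScfbaRun(config, net, star, data, g_off, model)

    base = apply_medium(build_population_model(star, data.n_cells), medium)
    capacities = compute_flux_capacities(base)
    ras = normalize_ras(compute_ras_matrix(star, data))
    model = apply_ras_bounds(base, capacities, ras, config.epsilon)
    return ScfbaRun(config, net, star, data, g_off, model, ras=ras, capacities=capacities)


def run_pipeline(
    net: TemplateNetwork,
    data: ExpressionData,
    medium: MediumSpec,
    config: RunConfig,
    out_dir: Optional[str] = None,
) -> ScfbaRun:
    """Prepare, optimize, and (optionally) write all tabular outputs."""
    run = prepare_run(net, data, medium, config)
    run.solution = optimize_population(run.model, config.objective, config.atp_species)
    if run.solution.status != "optimal":
        raise RuntimeError(
            f"optimization failed at the solve stage ({run.solution.status}); "
            "check medium bounds and epsilon"
        )
    if out_dir is not None:
        _write_outputs(run, Path(out_dir))
    return run


def epsilon_scan(
    net: TemplateNetwork,
    data: ExpressionData,
    medium: MediumSpec,
    config: RunConfig,
    epsilons: Sequence[float] = EPSILON_SCAN_VALUES,
) -> pd.DataFrame:
    """Total objective as a function of the epsilon floor (capacities reused)."""
    base_cfg = RunConfig(
        mode="scFBA",
        epsilon=max(epsilons),
        objective=config.objective,
        atp_species=config.atp_species,
        min_genes_detected=config.min_genes_detected,
        seed=config.seed,
    )
    run = prepare_run(net, data, medium, base_cfg)
    assert run.ras is not None and run.capacities is not None
    rows = []
    for eps in epsilons:
        base = apply_medium(
            build_population_model(run.template_star, run.expression.n_cells), medium
        )
        model = apply_ras_bounds(base, run.capacities, run.ras, eps)
        res = optimize_population(model, config.objective, config.atp_species)
        rows.append(
            {
                "epsilon": eps,
                "objective": res.objective_value if res.status == "optimal" else np.nan,
                "status": res.status,
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(run: ScfbaRun, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    assert run.solution is not None and run.solution.v is not None
    run.solution.flux_frame(run.model).to_csv(out_dir / "fluxes.tsv", sep="\t", index=False)
    if run.ras is not None:
        run.ras.ras.to_csv(out_dir / "ras.tsv", sep="\t")
        if run.ras.normalized is not None:
            run.ras.normalized.to_csv(out_dir / "ras_normalized.tsv", sep="\t")
    if run.capacities is not None:
        pd.DataFrame(
            {
                "F_forward": run.capacities.f_forward,
                "F_backward": run.capacities.f_backward,
                "capacity": run.capacities.capacity,
            }
        ).to_csv(out_dir / "capacities.tsv", sep="\t")
    provenance = {
        "config": {**run.config.__dict__},
        "config_hash": run.config.digest(),
        "n_cells": run.model.n_cells,
        "objective_value": run.solution.objective_value,
        "g_off": sorted(run.g_off),
        "solver": "scipy-highs",
        "feasibility_tol": 1e-9,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))


def per_cell_flux_matrix(run: ScfbaRun) -> pd.DataFrame:
    """Template-reaction x cell flux matrix from the solved run.

    Rows are internal template reactions plus cooperation fluxes (prefixed
    ``coop_``); suitable as clustering features.
    """
    if run.solution is None or run.solution.v is None:
        raise ValueError("run is not solved")
    model, v = run.model, run.solution.v
    rows = {}
    for rxn in model.template.reactions:
        rows[rxn.id] = [v[model.column("internal", c, rxn.id)] for c in range(1, model.n_cells + 1)]
    for species in model.tme_species:
        rows[f"coop_{species}"] = [
            v[model.column("cooperation", c, species)] for c in range(1, model.n_cells + 1)
        ]
    cells = run.expression.cells if run.expression.n_cells == model.n_cells else list(
        range(1, model.n_cells + 1)
    )
    return pd.DataFrame.from_dict(rows, orient="index", columns=cells)
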