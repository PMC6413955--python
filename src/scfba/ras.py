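"""Reaction activity scores (RAS) from GPR rules and per-cell transcript levels.

For one cell, a reaction scores ``min`` of its AND-joined subunit transcript
levels and ``sum`` of its OR-joined isoform levels, recursively for composite
rules.  Scores are then normalized per reaction across cells (each reaction's
scores divided by their total), giving the share of the reaction's total
activity attributable to each cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import FrozenSet, Mapping, Optional

import numpy as np
import pandas as pd

from .expression import ExpressionData
from .gpr import BoolOp, Gene, GPRRule
from .network import TemplateNetwork

__all__ = ["RASMatrix", "eval_ras", "compute_ras_matrix", "normalize_ras"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RASMatrix:
    """Reactions x cells activity scores, optionally with their normalization."""

    ras: pd.DataFrame  # scored reactions x cells, >= 0
    normalized: Optional[pd.DataFrame] = None  # same shape, rows sum to 1 (or 0)

    @property
    def scored_reactions(self) -> FrozenSet[str]:
        return frozenset(self.ras.index)

    @property
    def cells(self) -> list:
        return list(self.ras.columns)


def eval_ras(rule: GPRRule, expr: Mapping[str, float]) -> Optional[float]:
    """Score one rule for one cell's gene -> TPM mapping.

    AND nodes take the minimum of their children (limiting subunit), OR nodes
    the sum (additive isoforms).  Genes absent from *expr* are non-limiting:
    they are skipped in AND nodes and dropped from OR sums.  When every gene
    of the rule is absent the result is ``None`` (unscorable).
    """
    if isinstance(rule, Gene):
        value = expr.get(rule.name)
        return None if value is None else float(value)
    scores = [eval_ras(child, expr) for child in rule.children]
    present = [s for s in scores if s is not None]
    if not present:
        return None
    return min(present) if rule.op == "and" else sum(present)


def compute_ras_matrix(net: TemplateNetwork, data: ExpressionData) -> RASMatrix:
    """Score every reaction of *net* with a usable GPR against every cell.

    A reaction is scored when it carries a GPR whose gene set intersects the
    expression matrix; reactions without a GPR (including those whose GPR was
    excluded at load time) are unscored.  Exchange reactions with a GPR
    (transporters) are scored too, so their cooperation counterparts can be
    bounded.
    """
    if data.gene_status is None:
        log.warning("compute_ras_matrix: expression data was not reconciled against bulk")
    measured = set(data.values.index)
    cells = data.values.columns
    expr_by_cell = [data.values[c].to_dict() for c in cells]

    rows = {}
    skipped = 0
    for rxn in list(net.reactions) + list(net.exchanges):
        if rxn.gpr is None:
            continue
        if not (rxn.genes & measured):
            skipped += 1
            continue
        rows[rxn.id] = [eval_ras(rxn.gpr, expr) for expr in expr_by_cell]
    if skipped:
        log.info("compute_ras_matrix: %d GPR reactions had no measured genes", skipped)
    ras = pd.DataFrame.from_dict(rows, orient="index", columns=list(cells), dtype=float)
    return RASMatrix(ras=ras)


def normalize_ras(ras: RASMatrix) -> RASMatrix:
    """Divide each reaction's scores by their total across cells.

    All-zero rows (every cell scores 0) stay all-zero; the bounds module then
    assigns those cells the epsilon floor.
    """
    totals = ras.ras.sum(axis=1)
    normalized = ras.ras.div(totals.where(totals > 0), axis=0).fillna(0.0)
    return replace(ras, normalized=normalized)
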