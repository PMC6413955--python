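"""Self-contained synthetic fixtures: a toy metabolic network with cooperation
potential and a matched single-cell expression matrix with known
subpopulation structure.

The ``glycolysis_oxphos_toy`` variant has a fermentative route (glucose ->
lactate, redox-forced overflow), an oxygen-requiring oxidative route that can
also run on imported lactate, and a palmitate-like synthesis/uptake pair that
feeds biomass.  GPRs deliberately cover an OR pair (isoforms, one never
measured), AND pairs (subunits), and one composite rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import ExpressionData
from .gpr import parse_gpr
from .network import Reaction, TemplateNetwork
from .population import MediumSpec

__all__ = ["FixtureSpec", "make_toy_network", "simulate_expression", "default_medium"]

#: per-subpopulation mean TPM programs for the toy network's genes.
#: gA2 (the silent isoform of gA1) is intentionally absent: it exists only in
#: the GPR, mimicking an unmeasured gene.
_PROGRAMS: Dict[str, Dict[str, float]] = {
    "glycolytic": {
        "gA1": 100.0, "gB1": 100.0, "gL1": 80.0,
        "gR1": 1.0, "gR2": 1.0, "gN1": 1.0,
        "gP1": 60.0, "gP2": 60.0, "gZ1": 100.0, "gZ2": 20.0, "gX1": 0.0,
    },
    "oxidative": {
        "gA1": 6.0, "gB1": 10.0, "gL1": 80.0,
        "gR1": 100.0, "gR2": 100.0, "gN1": 100.0,
        "gP1": 60.0, "gP2": 60.0, "gZ1": 100.0, "gZ2": 20.0, "gX1": 0.0,
    },
}


#: TPM scale of the dropout decay (dropout is rare above a few tens of TPM)
_DROPOUT_DECAY_TPM = 10.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic expression matrix."""

    n_cells: int = 20
    n_subpops: int = 2
    proportions: Optional[Sequence[float]] = None  # defaults to equal split
    dropout_rate: float = 0.3
    expression_scale: float = 1.0
    noise_sigma: float = 0.25
    cell_factor_sigma: float = 0.0  # lognormal per-cell size factor shared by all genes
    seed: int = 0
    network_variant: str = "glycolysis_oxphos_toy"

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.proportions is not None:
            if len(self.proportions) != self.n_subpops:
                raise ValueError("proportions must match n_subpops")
            if abs(sum(self.proportions) - 1.0) > 1e-9:
                raise ValueError("proportions must sum to 1")


def make_toy_network(variant: str = "glycolysis_oxphos_toy") -> TemplateNetwork:
    """Build a small template network for tests and simulations."""
    if variant == "chain":
        return _chain_network()
    if variant == "glycolysis_oxphos_toy":
        return _glycolysis_oxphos_toy()
    raise ValueError(f"unknown network variant {variant!r}")


def _chain_network() -> TemplateNetwork:
    # uptake -> a -> b -> biomass sink; every step carries the same flux
    rxn = lambda rid, stoich, gpr, rev=False: Reaction(
        id=rid,
        stoichiometry=stoich,
        reversible=rev,
        gpr=parse_gpr(gpr) if gpr else None,
        lb=-1000.0 if rev else 0.0,
        ub=1000.0,
    )
    return TemplateNetwork(
        metabolites=["a", "b", "bio"],
        reactions=[
            rxn("R1", {"a": -1, "b": 1}, "g1"),
            rxn("R2", {"b": -1, "bio": 1}, "g2"),
        ],
        exchanges=[
            rxn("EX_a", {"a": -1}, None, rev=True),
            rxn("EX_bio", {"bio": -1}, None, rev=True),
        ],
        biomass_reaction_id="R2",
    )


def _glycolysis_oxphos_toy() -> TemplateNetwork:
    def rxn(rid, stoich, gpr, rev=False):
        return Reaction(
            id=rid,
            stoichiometry=stoich,
            reversible=rev,
            gpr=parse_gpr(gpr) if gpr else None,
            lb=-1000.0 if rev else 0.0,
            ub=1000.0,
        )

    metabolites = ["glc", "tp", "pyr", "lac", "o2", "nadh", "atp", "pal", "bio"]
    reactions = [
        # two lumped glycolysis steps; GLY1 has an isoform pair (gA2 silent)
        rxn("GLY1", {"glc": -1, "tp": 2}, "gA1 or gA2"),
        rxn("GLY2", {"tp": -1, "pyr": 1, "atp": 1, "nadh": 1}, "gB1"),
        # fermentation, reversible: forward is the redox-overflow sink,
        # backward lets a cell run on imported lactate
        rxn("LDH", {"pyr": -1, "nadh": -2, "lac": 1}, "gL1", rev=True),
        # oxidative route: AND subunits, oxygen-dependent, high ATP yield
        rxn("RESP", {"pyr": -1, "nadh": -1, "o2": -3, "atp": 8}, "gR1 and gR2"),
        # NADH oxidase: redox valve burning oxygen
        rxn("NOX", {"nadh": -2, "o2": -1}, "gN1"),
        # palmitate-like synthesis (AND pair) feeding biomass
        rxn("PALS", {"pyr": -1, "atp": -2, "pal": 1}, "gP1 and gP2"),
        # wasteful bypass, off in every cell of every program (G_off target)
        rxn("GLYX", {"glc": -1, "lac": 1}, "gX1"),
        # biomass synthesis; composite GPR exercises AND-over-OR
        rxn("BIOSYN", {"pyr": -1, "atp": -2, "pal": -1, "bio": 1}, "gZ1 and (gB1 or gZ2)"),
    ]
    exchanges = [
        rxn("EX_glc", {"glc": -1}, None, rev=True),
        rxn("EX_o2", {"o2": -1}, None, rev=True),
        rxn("EX_lac", {"lac": -1}, None, rev=True),
        rxn("EX_pal", {"pal": -1}, None, rev=True),
        rxn("EX_bio", {"bio": -1}, None, rev=True),
    ]
    return TemplateNetwork(
        metabolites=metabolites,
        reactions=reactions,
        exchanges=exchanges,
        biomass_reaction_id="BIOSYN",
    )


def default_medium(n_pop: int, *, exogenous_palmitate: bool = False,
                   exogenous_lactate: bool = False, oxygen: bool = True) -> MediumSpec:
    """Baseline boundary configuration for the toy network."""
    uptake = {"glc": 10.0}
    if oxygen:
        uptake["o2"] = 10.0
    if exogenous_palmitate:
        uptake["pal"] = 10.0
    if exogenous_lactate:
        uptake["lac"] = 10.0
    return MediumSpec(
        uptake=uptake,
        secretable_to_blood={"lac", "pal"},
        secretable_to_tme={"lac", "pal"},
        n_pop=n_pop,
    )


def simulate_expression(
    net: TemplateNetwork, spec: FixtureSpec
) -> Tuple[ExpressionData, pd.Series]:
    """Simulate a genes x cells TPM matrix with known subpopulation labels.

    Each subpopulation expresses its program's mean TPM per gene, perturbed by
    multiplicative lognormal noise; zeros are injected at ``dropout_rate``.
    The bulk profile is the per-gene mean of the pre-dropout matrix (so a gene
    dropped everywhere is still visibly expressed in bulk).  Deterministic for
    a given seed.  Returns the expression data and the true labels.
    """
    rng = np.random.default_rng(spec.seed)
    program_names = list(_PROGRAMS)[: spec.n_subpops]
    if spec.n_subpops > len(_PROGRAMS):
        raise ValueError(f"at most {len(_PROGRAMS)} subpopulations are programmed")
    proportions = (
        list(spec.proportions)
        if spec.proportions is not None
        else [1.0 / spec.n_subpops] * spec.n_subpops
    )
    counts = _allocate(spec.n_cells, proportions)
    labels = pd.Series(
        np.repeat(program_names, counts),
        index=[f"cell{i + 1}" for i in range(spec.n_cells)],
        name="subpop",
    )

    genes = list(_PROGRAMS[program_names[0]])
    means = np.column_stack(
        [
            np.array([_PROGRAMS[labels.iloc[c]][g] for g in genes])
            for c in range(spec.n_cells)
        ]
    ) * spec.expression_scale

    noisy = means.copy()
    if spec.noise_sigma > 0:
        noisy = noisy * rng.lognormal(mean=0.0, sigma=spec.noise_sigma, size=means.shape)
    if spec.cell_factor_sigma > 0:
        factors = rng.lognormal(mean=0.0, sigma=spec.cell_factor_sigma, size=spec.n_cells)
        noisy = noisy * factors[np.newaxis, :]
    noisy[means == 0] = 0.0

    bulk = pd.Series(noisy.mean(axis=1), index=genes, name="bulk")

    observed = noisy.copy()
    if spec.dropout_rate > 0:
        # expression-dependent dropout: the configured rate applies to weakly
        # expressed genes and decays exponentially with the true signal, as in
        # scRNA-seq capture models
        p_drop = spec.dropout_rate * np.exp(-noisy / _DROPOUT_DECAY_TPM)
        drop = rng.random(size=observed.shape) < p_drop
        observed[drop] = 0.0

    values = pd.DataFrame(observed, index=genes, columns=labels.index)
    return ExpressionData(values=values, bulk=bulk), labels


def _allocate(n: int, proportions: List[float]) -> List[int]:
    counts = [int(round(p * n)) for p in proportions]
    while sum(counts) < n:
        counts[int(np.argmax(proportions))] += 1
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    if min(counts) < 1:
        raise ValueError("each subpopulation needs at least one cell")
    return counts
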