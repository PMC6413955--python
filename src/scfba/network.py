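"""Template metabolic network: SBML IO, exchange detection, gene deletion.

The template network ``A`` consists of metabolites, internal reactions and
exchange reactions (unbalanced, single-metabolite reactions that insert or
remove boundary species, including the biomass pseudo-metabolite).  SBML
reading/writing is delegated to cobrapy; GPR strings are re-parsed into the
package's own evaluable trees (:mod:`scfba.gpr`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set

from .gpr import GPRRule, parse_gpr, simplify_without

__all__ = [
    "Reaction",
    "TemplateNetwork",
    "read_template_network",
    "write_template_network",
    "delete_genes",
]


@dataclass(frozen=True)
class Reaction:
    """One reaction record of the template network."""

    id: str
    stoichiometry: Mapping[str, float]  # metabolite id -> coefficient
    reversible: bool
    gpr: Optional[GPRRule] = None
    lb: float = 0.0
    ub: float = 1000.0

    @property
    def genes(self) -> FrozenSet[str]:
        return self.gpr.genes() if self.gpr is not None else frozenset()


@dataclass(frozen=True)
class TemplateNetwork:
    """The single-cell map ``A = (X_A, R_A, E_A)``.

    ``reactions`` holds the N internal reactions, ``exchanges`` the N_ext
    unbalanced boundary reactions (each touching exactly one metabolite).
    ``biomass_reaction_id`` names the internal reaction producing the biomass
    pseudo-metabolite.
    """

    metabolites: List[str]
    reactions: List[Reaction]
    exchanges: List[Reaction]
    biomass_reaction_id: str
    gpr_excluded_reactions: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        known = set(self.metabolites)
        for rxn in list(self.reactions) + list(self.exchanges):
            unknown = set(rxn.stoichiometry) - known
            if unknown:
                raise ValueError(f"reaction {rxn.id}: unknown metabolites {sorted(unknown)}")
        for exch in self.exchanges:
            if len(exch.stoichiometry) != 1:
                raise ValueError(f"exchange {exch.id} must touch exactly one metabolite")
        internal_ids = {r.id for r in self.reactions}
        if self.biomass_reaction_id not in internal_ids:
            raise ValueError(f"biomass reaction {self.biomass_reaction_id!r} not an internal reaction")
        if internal_ids & {e.id for e in self.exchanges}:
            raise ValueError("exchange and internal reaction ids overlap")

    # -- convenience sizes -------------------------------------------------
    @property
    def n_metabolites(self) -> int:  # M
        return len(self.metabolites)

    @property
    def n_internal(self) -> int:  # N
        return len(self.reactions)

    @property
    def n_exchanges(self) -> int:  # N_ext
        return len(self.exchanges)

    @property
    def exchanged_species(self) -> List[str]:
        """Boundary metabolites Y, in exchange order."""
        return [next(iter(e.stoichiometry)) for e in self.exchanges]

    @property
    def genes(self) -> FrozenSet[str]:
        out: FrozenSet[str] = frozenset()
        for rxn in list(self.reactions) + list(self.exchanges):
            out = out | rxn.genes
        return out

    def reaction(self, rid: str) -> Reaction:
        for rxn in list(self.reactions) + list(self.exchanges):
            if rxn.id == rid:
                return rxn
        raise KeyError(rid)

    def to_json(self) -> str:
        """Debug dump of the parsed network."""
        def rec(r: Reaction) -> dict:
            return {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "reversible": r.reversible,
                "gpr": r.gpr.to_string() if r.gpr is not None else None,
                "lb": r.lb,
                "ub": r.ub,
            }

        return json.dumps(
            {
                "metabolites": self.metabolites,
                "reactions": [rec(r) for r in self.reactions],
                "exchanges": [rec(r) for r in self.exchanges],
                "biomass_reaction_id": self.biomass_reaction_id,
                "gpr_excluded_reactions": sorted(self.gpr_excluded_reactions),
            },
            indent=2,
        )


def _is_exchange(cobra_rxn) -> bool:
    return len(cobra_rxn.metabolites) == 1


def read_template_network(
    path: str,
    gpr_excluded: Optional[Set[str]] = None,
    *,
    biomass_reaction_id: Optional[str] = None,
    exchange_override: Optional[Sequence[str]] = None,
    gene_mapping: Optional[Mapping[str, str]] = None,
) -> TemplateNetwork:
    """Read an SBML file into a :class:`TemplateNetwork`.

    Exchange reactions are auto-detected as reactions with exactly one
    metabolite participant; *exchange_override*, when given, wins.  Reactions
    listed in *gpr_excluded* carry no GPR (their rule is disregarded when
    scoring).  Reversibility is taken from the bounds (``lb < 0``), falling
    back to the SBML ``reversible`` attribute when bounds are absent.
    *gene_mapping* optionally renames gene IDs (e.g. Ensembl to HGNC) at load
    time.
    """
    import cobra.io

    gpr_excluded = set(gpr_excluded or ())
    model = cobra.io.read_sbml_model(path)

    known_rids = {r.id for r in model.reactions}
    missing = gpr_excluded - known_rids
    if missing:
        raise ValueError(f"gpr_excluded names unknown reactions: {sorted(missing)}")

    metabolites = [m.id for m in model.metabolites]
    internal: List[Reaction] = []
    exchanges: List[Reaction] = []
    override = set(exchange_override) if exchange_override is not None else None

    for rxn in model.reactions:
        gpr_text = str(rxn.gpr).strip() if rxn.gpr is not None else ""
        rule: Optional[GPRRule] = None
        if gpr_text and rxn.id not in gpr_excluded:
            try:
                rule = parse_gpr(gpr_text)
            except Exception as exc:  # re-raise naming the reaction
                raise ValueError(f"unresolvable GPR for reaction {rxn.id!r}: {exc}") from exc
            if gene_mapping:
                rule = _rename_genes(rule, gene_mapping)
        lb, ub = float(rxn.lower_bound), float(rxn.upper_bound)
        record = Reaction(
            id=rxn.id,
            stoichiometry={m.id: float(c) for m, c in rxn.metabolites.items()},
            reversible=(lb < 0),
            gpr=rule,
            lb=lb,
            ub=ub,
        )
        is_exch = rxn.id in override if override is not None else _is_exchange(rxn)
        (exchanges if is_exch else internal).append(record)

    if biomass_reaction_id is None:
        biomass_reaction_id = _guess_biomass(internal)
    return TemplateNetwork(
        metabolites=metabolites,
        reactions=internal,
        exchanges=exchanges,
        biomass_reaction_id=biomass_reaction_id,
        gpr_excluded_reactions=frozenset(gpr_excluded),
    )


def _rename_genes(rule: GPRRule, mapping: Mapping[str, str]) -> GPRRule:
    from .gpr import BoolOp, Gene

    if isinstance(rule, Gene):
        return Gene(mapping.get(rule.name, rule.name))
    return BoolOp(rule.op, tuple(_rename_genes(c, mapping) for c in rule.children))


def _guess_biomass(reactions: Sequence[Reaction]) -> str:
    markers = ("biomass", "biosyn", "growth")
    candidates = [r.id for r in reactions if any(m in r.id.lower() for m in markers)]
    if len(candidates) != 1:
        raise ValueError(
            "cannot identify a unique biomass reaction; pass biomass_reaction_id "
            f"(candidates: {candidates})"
        )
    return candidates[0]


def write_template_network(net: TemplateNetwork, path: str) -> None:
    """Write the network as SBML Level 3 + fbc (via cobrapy)."""
    import cobra
    import cobra.io

    model = cobra.Model("template")
    mets = {mid: cobra.Metabolite(mid, compartment="c") for mid in net.metabolites}
    for rec in list(net.reactions) + list(net.exchanges):
        rxn = cobra.Reaction(rec.id, lower_bound=rec.lb, upper_bound=rec.ub)
        model.add_reactions([rxn])
        rxn.add_metabolites({mets[m]: c for m, c in rec.stoichiometry.items()})
        if rec.gpr is not None:
            rxn.gene_reaction_rule = rec.gpr.to_string()
    model.objective = net.biomass_reaction_id
    cobra.io.write_sbml_model(model, path)


def delete_genes(net: TemplateNetwork, genes: Set[str]) -> TemplateNetwork:
    """Return the subnetwork with *genes* knocked out.

    Each GPR is partially evaluated with the deleted genes fixed to FALSE
    (other genes TRUE); reactions whose rule becomes unsatisfiable are
    removed, and their deleted leaves are pruned from surviving rules so that
    deletion composes (``delete(G1 ∪ G2) == delete(delete(G1), G2)``).
    Reactions without a GPR are untouched; metabolites no longer referenced by
    any reaction are dropped, along with their exchanges.
    """
    absent = frozenset(genes)
    if not absent:
        return net

    survivors: List[Reaction] = []
    for rxn in net.reactions:
        if rxn.gpr is None:
            survivors.append(rxn)
            continue
        simplified = simplify_without(rxn.gpr, absent)
        if simplified is None:
            continue
        survivors.append(replace(rxn, gpr=simplified))

    if not any(r.id == net.biomass_reaction_id for r in survivors):
        raise ValueError("gene deletion removed the biomass reaction itself")

    referenced = set()
    for rxn in survivors:
        referenced.update(rxn.stoichiometry)
    kept_exchanges = []
    for exch in net.exchanges:
        species = next(iter(exch.stoichiometry))
        if species in referenced:
            new_gpr = None
            if exch.gpr is not None:
                new_gpr = simplify_without(exch.gpr, absent)
                if new_gpr is None:
                    continue
            kept_exchanges.append(replace(exch, gpr=new_gpr))
    metabolites = [m for m in net.metabolites if m in referenced]

    return TemplateNetwork(
        metabolites=metabolites,
        reactions=survivors,
        exchanges=kept_exchanges,
        biomass_reaction_id=net.biomass_reaction_id,
        gpr_excluded_reactions=net.gpr_excluded_reactions,
    )


def disabled_reactions(net: TemplateNetwork, genes: Set[str]) -> Set[str]:
    """Reaction IDs whose GPR becomes unsatisfiable when *genes* are FALSE."""
    absent = frozenset(genes)
    out: Set[str] = set()
    for rxn in list(net.reactions) + list(net.exchanges):
        if rxn.gpr is not None and simplify_without(rxn.gpr, absent) is None:
            out.add(rxn.id)
    return out
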