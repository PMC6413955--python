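"""Multi-scale population model: N cell replicates coupled through a shared
microenvironment (TME) compartment.

Each cell is a copy of the template network whose exchange reactions are
replaced by *cooperation* reactions moving the species between the cell's
boundary pool and a shared TME pool (``Y_j^cell <-> Y_j^TME``, reversible,
positive flux = secretion into the TME).  Every TME species is drained/fed by
a *blood* exchange (``Y_j^TME -> nothing``, negative flux = uptake from
blood).  The biomass pseudo-metabolite follows the same plumbing: per-cell
biomass flows into a TME biomass pool whose blood exchange is the default
objective, so the objective value is the total biomass of the population.

Column order is stable: all cell-1 internal columns (template order), cell-1
cooperation columns (exchange order), ..., cell-N columns, then blood
columns; medium application may append per-cell direct secretion columns and
the ATP objective appends per-cell demand columns.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp

from .network import TemplateNetwork

__all__ = ["ColumnMeta", "PopulationModel", "MediumSpec", "build_population_model", "apply_medium"]

#: large-but-finite default span for cooperation columns (keeps FVA bounded)
_DEFAULT_COOP_BOUND = 1000.0


@dataclass(frozen=True)
class ColumnMeta:
    """What one flux column represents.

    kind: ``internal`` | ``cooperation`` | ``secretion`` | ``demand`` | ``blood``;
    cell: 1-based cell index (None for blood columns);
    ref: template reaction id (internal) or species id (other kinds).
    """

    kind: str
    cell: Optional[int]
    ref: str

    @property
    def name(self) -> str:
        if self.kind == "internal":
            return f"{self.ref}_cell{self.cell}"
        if self.kind == "cooperation":
            return f"coop_{self.ref}_cell{self.cell}"
        if self.kind == "secretion":
            return f"sec_{self.ref}_cell{self.cell}"
        if self.kind == "demand":
            return f"demand_{self.ref}_cell{self.cell}"
        return f"blood_{self.ref}"


@dataclass
class MediumSpec:
    """Type-1 (population boundary) constraints.

    *uptake* maps species to a per-cell maximal uptake rate (nmol/h), scaled
    by *n_pop*; *secretable_to_blood* species get an open blood secretion
    bound plus a per-cell direct secretion reaction; *secretable_to_tme*
    species are the designated cooperation species (the ones blocked by a
    cooperation knockout).  All other blood exchanges are closed.
    """

    uptake: Dict[str, float] = field(default_factory=dict)
    secretable_to_blood: Set[str] = field(default_factory=set)
    secretable_to_tme: Set[str] = field(default_factory=set)
    n_pop: int = 1

    def __post_init__(self) -> None:
        for species, rate in self.uptake.items():
            if rate < 0:
                raise ValueError(f"uptake rate for {species!r} must be >= 0")
        if self.n_pop < 1:
            raise ValueError("n_pop must be >= 1")


@dataclass
class PopulationModel:
    """Sparse stoichiometric population model with per-column bounds."""

    template: TemplateNetwork
    n_cells: int
    S: sp.csc_matrix  # rows: cell metabolites then TME species
    row_ids: List[str]
    columns: List[ColumnMeta]
    lb: np.ndarray
    ub: np.ndarray
    tme_species: List[str]  # exchange order
    blood_species: List[str]
    objective_cols: List[int]
    biomass_species: str
    medium: Optional[MediumSpec] = None
    col_index: Dict[Tuple[str, Optional[int], str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.col_index:
            self.col_index = {(c.kind, c.cell, c.ref): i for i, c in enumerate(self.columns)}

    # -- lookups -----------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int]:
        return self.S.shape

    @property
    def column_names(self) -> List[str]:
        return [c.name for c in self.columns]

    def column(self, kind: str, cell: Optional[int], ref: str) -> int:
        return self.col_index[(kind, cell, ref)]

    def internal_columns(self, rid: str) -> List[int]:
        return [self.column("internal", c, rid) for c in range(1, self.n_cells + 1)]

    def cooperation_columns(self, species: str) -> List[int]:
        return [self.column("cooperation", c, species) for c in range(1, self.n_cells + 1)]

    def biomass_columns(self) -> List[int]:
        """Per-cell biomass contribution fluxes (the biomass cooperation columns)."""
        return self.cooperation_columns(self.biomass_species)

    def copy(self) -> "PopulationModel":
        return PopulationModel(
            template=self.template,
            n_cells=self.n_cells,
            S=self.S,
            row_ids=self.row_ids,
            columns=self.columns,
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            tme_species=list(self.tme_species),
            blood_species=list(self.blood_species),
            objective_cols=list(self.objective_cols),
            biomass_species=self.biomass_species,
            medium=_copy.deepcopy(self.medium),
            col_index=self.col_index,
        )

    def with_extra_columns(
        self,
        metas: Sequence[ColumnMeta],
        stoichs: Sequence[Mapping[str, float]],
        lbs: Sequence[float],
        ubs: Sequence[float],
    ) -> "PopulationModel":
        """Return a copy with appended columns (row space unchanged)."""
        row_pos = {rid: i for i, rid in enumerate(self.row_ids)}
        extra = sp.lil_matrix((len(self.row_ids), len(metas)))
        for j, stoich in enumerate(stoichs):
            for rid, coeff in stoich.items():
                extra[row_pos[rid], j] = coeff
        model = self.copy()
        model.S = sp.hstack([self.S, extra.tocsc()], format="csc")
        model.columns = list(self.columns) + list(metas)
        model.lb = np.concatenate([self.lb, np.asarray(lbs, dtype=float)])
        model.ub = np.concatenate([self.ub, np.asarray(ubs, dtype=float)])
        model.col_index = {(c.kind, c.cell, c.ref): i for i, c in enumerate(model.columns)}
        return model


def build_population_model(
    net: TemplateNetwork,
    n_cells: int,
    blood_metabolites: Optional[Sequence[str]] = None,
) -> PopulationModel:
    """Assemble the population model from *n_cells* replicates of *net*.

    Every exchanged species gets one TME pool row; by default every TME
    species also gets a blood exchange (closed or opened later by the
    medium), which makes the matrix exactly
    ``(n_cells*M + N_blood) x (n_cells*(N + N_ext) + N_blood)`` with
    ``N_blood == N_ext``.  Passing an explicit *blood_metabolites* subset
    restricts the blood columns; TME rows are kept for all exchanged species
    regardless, since cooperation fluxes must stay mass-balanced.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    species_order = net.exchanged_species
    if blood_metabolites is None:
        blood = list(species_order)
    else:
        blood = list(blood_metabolites)
        unknown = set(blood) - set(species_order)
        if unknown:
            raise ValueError(f"blood metabolites without a TME counterpart: {sorted(unknown)}")

    biomass_species = _biomass_species(net)
    if blood_metabolites is not None and biomass_species not in blood:
        raise ValueError("blood metabolites must include the biomass species (objective route)")

    met_pos = {m: i for i, m in enumerate(net.metabolites)}
    n_rows = n_cells * net.n_metabolites + len(species_order)
    row_ids = [
        f"{m}_cell{c}" for c in range(1, n_cells + 1) for m in net.metabolites
    ] + [f"{s}_TME" for s in species_order]
    tme_row = {s: n_cells * net.n_metabolites + i for i, s in enumerate(species_order)}

    data: List[float] = []
    rows: List[int] = []
    cols: List[int] = []
    metas: List[ColumnMeta] = []
    lbs: List[float] = []
    ubs: List[float] = []

    def add_entry(r: int, value: float) -> None:
        rows.append(r)
        cols.append(len(metas))
        data.append(value)

    for c in range(1, n_cells + 1):
        offset = (c - 1) * net.n_metabolites
        for rxn in net.reactions:
            for m, coeff in rxn.stoichiometry.items():
                add_entry(offset + met_pos[m], coeff)
            metas.append(ColumnMeta("internal", c, rxn.id))
            lbs.append(rxn.lb)
            ubs.append(rxn.ub)
        for exch in net.exchanges:
            species = next(iter(exch.stoichiometry))
            add_entry(offset + met_pos[species], -1.0)
            add_entry(tme_row[species], +1.0)
            metas.append(ColumnMeta("cooperation", c, species))
            span = max(abs(exch.lb), abs(exch.ub), _DEFAULT_COOP_BOUND)
            lbs.append(-span)
            ubs.append(span)

    exch_by_species = {next(iter(e.stoichiometry)): e for e in net.exchanges}
    for species in blood:
        add_entry(tme_row[species], -1.0)
        metas.append(ColumnMeta("blood", None, species))
        exch = exch_by_species[species]
        lbs.append(exch.lb)
        ubs.append(exch.ub)

    S = sp.coo_matrix((data, (rows, cols)), shape=(n_rows, len(metas))).tocsc()
    model = PopulationModel(
        template=net,
        n_cells=n_cells,
        S=S,
        row_ids=row_ids,
        columns=metas,
        lb=np.asarray(lbs, dtype=float),
        ub=np.asarray(ubs, dtype=float),
        tme_species=list(species_order),
        blood_species=blood,
        objective_cols=[],
        biomass_species=biomass_species,
    )
    model.objective_cols = [model.column("blood", None, biomass_species)]
    return model


def _biomass_species(net: TemplateNetwork) -> str:
    """The exchanged species produced by the biomass reaction."""
    biomass = net.reaction(net.biomass_reaction_id)
    produced = {m for m, coeff in biomass.stoichiometry.items() if coeff > 0}
    candidates = [s for s in net.exchanged_species if s in produced]
    if len(candidates) != 1:
        raise ValueError(
            "biomass reaction must produce exactly one exchanged pseudo-metabolite; "
            f"found {candidates}"
        )
    return candidates[0]


def apply_medium(model: PopulationModel, medium: MediumSpec) -> PopulationModel:
    """Impose type-1 constraints and the dual secretion routes.

    Uptake species get blood bounds ``[-n_pop * rate, 0]``; species secretable
    to blood get an unbounded blood secretion route *and* one direct
    (irreversible) secretion reaction per cell, so that a later cooperation
    knockout still lets cells shed excess metabolites.  All other blood
    exchanges are closed; the biomass blood exchange stays open (objective).
    """
    known = set(model.tme_species)
    for group in (set(medium.uptake), medium.secretable_to_blood, medium.secretable_to_tme):
        unknown = set(group) - known
        if unknown:
            raise ValueError(f"medium names unknown species: {sorted(unknown)}")

    out = model.copy()
    for species in out.blood_species:
        j = out.column("blood", None, species)
        if species == out.biomass_species:
            out.lb[j], out.ub[j] = 0.0, np.inf
            continue
        lo, hi = 0.0, 0.0
        if species in medium.uptake:
            lo = -medium.n_pop * medium.uptake[species]
        if species in medium.secretable_to_blood:
            hi = np.inf
        out.lb[j], out.ub[j] = lo, hi

    direct = sorted(medium.secretable_to_blood)
    if direct:
        metas, stoichs, lbs, ubs = [], [], [], []
        for c in range(1, out.n_cells + 1):
            for species in direct:
                metas.append(ColumnMeta("secretion", c, species))
                stoichs.append({f"{species}_cell{c}": -1.0})
                lbs.append(0.0)
                ubs.append(np.inf)
        out = out.with_extra_columns(metas, stoichs, lbs, ubs)
    out.medium = medium
    return out


def add_atp_demand(model: PopulationModel, atp_species: str) -> PopulationModel:
    """Append one ATP demand (hydrolysis-style drain) column per cell.

    The demand consumes the cell's ATP pool; maximizing the sum of these
    columns is the population ATP-production objective.
    """
    if atp_species not in model.template.metabolites:
        raise ValueError(f"unknown ATP species {atp_species!r}")
    metas, stoichs = [], []
    for c in range(1, model.n_cells + 1):
        metas.append(ColumnMeta("demand", c, atp_species))
        stoichs.append({f"{atp_species}_cell{c}": -1.0})
    out = model.with_extra_columns(
        metas, stoichs, [0.0] * model.n_cells, [np.inf] * model.n_cells
    )
    out.objective_cols = [out.column("demand", c, atp_species) for c in range(1, out.n_cells + 1)]
    return out
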