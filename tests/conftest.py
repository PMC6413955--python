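"""Shared fixtures and independent LP oracles for the test suite."""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pytest
from scipy.optimize import linprog

from scfba.network import Reaction, TemplateNetwork
from scfba.synthetic import FixtureSpec, default_medium, make_toy_network, simulate_expression


@pytest.fixture
def toy_net() -> TemplateNetwork:
    return make_toy_network("glycolysis_oxphos_toy")


@pytest.fixture
def chain_net() -> TemplateNetwork:
    return make_toy_network("chain")


@pytest.fixture
def het_fixture(toy_net):
    """Two-subpopulation expression data (no dropout; clean programs)."""
    spec = FixtureSpec(n_cells=10, dropout_rate=0.0, noise_sigma=0.25, seed=42)
    data, labels = simulate_expression(toy_net, spec)
    return data, labels


@pytest.fixture
def homog_fixture(toy_net):
    """Perfectly homogeneous population: identical transcriptome in all cells."""
    spec = FixtureSpec(n_cells=8, n_subpops=1, dropout_rate=0.0, noise_sigma=0.0, seed=7)
    data, labels = simulate_expression(toy_net, spec)
    return data, labels


# ---------------------------------------------------------------------------
# independent oracle: solve the raw template (or any matrix) with linprog
# directly, bypassing the package's model-assembly path entirely
# ---------------------------------------------------------------------------

def template_lp_oracle(
    net: TemplateNetwork,
    exchange_bounds: Dict[str, Tuple[float, float]],
    objective_rid: str,
    fix_objective_at: Optional[float] = None,
    extremize_rid: Optional[str] = None,
    sense: float = 1.0,
) -> float:
    """Brute-force LP on the template's stoichiometric matrix.

    Maximizes *objective_rid*; optionally pins it and extremizes another
    reaction (sense=+1 max, -1 min).
    """
    all_rxns = list(net.reactions) + list(net.exchanges)
    rids = [r.id for r in all_rxns]
    met_pos = {m: i for i, m in enumerate(net.metabolites)}
    S = np.zeros((net.n_metabolites, len(rids)))
    bounds = []
    for j, rxn in enumerate(all_rxns):
        for m, coeff in rxn.stoichiometry.items():
            S[met_pos[m], j] = coeff
        bounds.append(exchange_bounds.get(rxn.id, (rxn.lb, rxn.ub)))
    obj_col = rids.index(objective_rid)
    if fix_objective_at is not None:
        lo, hi = bounds[obj_col]
        bounds[obj_col] = (fix_objective_at - 1e-9, hi)
        target = rids.index(extremize_rid)
    else:
        target = obj_col
    c = np.zeros(len(rids))
    c[target] = -sense
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    assert res.status == 0, f"oracle LP not optimal: {res.message}"
    return float(-res.fun * sense)  # optimal value of the target flux


def random_template_network(rng: np.random.Generator) -> TemplateNetwork:
    """Random small valid template network (structure only, no LP use)."""
    M = int(rng.integers(3, 12))
    N = int(rng.integers(2, 15))
    N_ext = int(rng.integers(1, M + 1))
    mets = [f"m{i}" for i in range(M)]
    reactions = [
        Reaction("Rbio", {mets[1 % M]: -1.0, mets[0]: 1.0}, False, None, 0.0, 1000.0)
    ]
    for i in range(1, N):
        picks = rng.choice(M, size=min(M, 2), replace=False)
        stoich = {mets[picks[0]]: -1.0}
        if len(picks) > 1:
            stoich[mets[picks[1]]] = 1.0
        reactions.append(Reaction(f"R{i}", stoich, bool(rng.integers(2)), None, 0.0, 1000.0))
    exchanges = [
        Reaction(f"EX_{mets[i]}", {mets[i]: -1.0}, True, None, -1000.0, 1000.0)
        for i in range(N_ext)
    ]
    return TemplateNetwork(
        metabolites=mets,
        reactions=reactions,
        exchanges=exchanges,
        biomass_reaction_id="Rbio",
    )
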