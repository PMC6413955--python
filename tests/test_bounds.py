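"""Capacity estimation and score-to-bound remapping."""

import numpy as np
import pandas as pd
import pytest

from scfba.bounds import CapacityTable, apply_ras_bounds, compute_flux_capacities
from scfba.population import MediumSpec, apply_medium, build_population_model
from scfba.ras import RASMatrix, normalize_ras
from scfba.solve import optimize_population


def _chain_model(n_cells=1):
    from scfba.synthetic import make_toy_network

    net = make_toy_network("chain")
    medium = MediumSpec(uptake={"a": 10.0}, n_pop=n_cells)
    return net, apply_medium(build_population_model(net, n_cells), medium)


def _ras(rows, cells):
    return normalize_ras(RASMatrix(ras=pd.DataFrame(rows, columns=cells, dtype=float)))


class TestCapacities:
    def test_linear_chain_capacity(self):
        # uptake(<=10) -> a -> b -> sink: every step carries at most 10
        net, model = _chain_model()
        caps = compute_flux_capacities(model)
        assert caps.capacity["R1"] == pytest.approx(10.0)
        assert caps.capacity["R2"] == pytest.approx(10.0)

    def test_unreachable_reaction_zero_capacity(self):
        net, model = _chain_model()
        j = model.column("blood", None, "a")
        model.lb[j] = 0.0  # close the only uptake
        caps = compute_flux_capacities(model)
        assert caps.capacity["R1"] == 0.0
        assert caps.capacity["R2"] == 0.0

    def test_reversible_capacity_is_max_abs(self, toy_net):
        from scfba.synthetic import default_medium

        model = apply_medium(build_population_model(toy_net, 2), default_medium(n_pop=2))
        caps = compute_flux_capacities(model)
        lac = caps.capacity["LDH"]
        assert lac == pytest.approx(
            max(abs(caps.f_forward["LDH"]), abs(caps.f_backward["LDH"]))
        )

    def test_infeasible_medium_raises(self, chain_net):
        model = build_population_model(chain_net, 1)
        j = model.column("blood", None, "bio")
        model.lb[j] = 50.0  # demand flux that mass balance cannot supply
        model.ub[j] = 100.0
        k = model.column("blood", None, "a")
        model.lb[k] = 0.0
        model.ub[k] = 0.0
        with pytest.raises(ValueError, match="infeasible"):
            compute_flux_capacities(model)


class TestApplyBounds:
    def test_eq_arithmetic(self):
        # U = eps + (F - eps) * share = 25.00075 for F=100, share=0.25, eps=1e-3
        net, model = _chain_model(n_cells=4)
        caps = CapacityTable(
            f_forward=pd.Series({"R1": 100.0}),
            f_backward=pd.Series({"R1": 0.0}),
            capacity=pd.Series({"R1": 100.0}),
        )
        ras = _ras([[1.0, 1.0, 1.0, 1.0]], [f"c{i}" for i in range(4)])
        ras.normalized.index = ["R1"]
        ras.ras.index = ["R1"]
        out = apply_ras_bounds(model, caps, ras, epsilon=1e-3)
        j = out.column("internal", 1, "R1")
        assert out.ub[j] == pytest.approx(1e-3 + (100.0 - 1e-3) * 0.25, abs=1e-15)
        assert out.ub[j] == pytest.approx(25.00075)

    def test_zero_share_gets_epsilon_floor(self):
        net, model = _chain_model(n_cells=2)
        caps = CapacityTable(
            f_forward=pd.Series({"R1": 50.0}),
            f_backward=pd.Series({"R1": 0.0}),
            capacity=pd.Series({"R1": 50.0}),
        )
        ras = _ras([[0.0, 3.0]], ["c1", "c2"])
        ras.normalized.index = ["R1"]
        ras.ras.index = ["R1"]
        out = apply_ras_bounds(model, caps, ras, epsilon=1e-3)
        assert out.ub[out.column("internal", 1, "R1")] == pytest.approx(1e-3)

    def test_epsilon_zero_full_share_recovers_capacity(self):
        net, model = _chain_model(n_cells=1)
        caps = CapacityTable(
            f_forward=pd.Series({"R1": 42.0}),
            f_backward=pd.Series({"R1": 0.0}),
            capacity=pd.Series({"R1": 42.0}),
        )
        ras = _ras([[5.0]], ["c1"])
        ras.normalized.index = ["R1"]
        ras.ras.index = ["R1"]
        out = apply_ras_bounds(model, caps, ras, epsilon=0.0)
        assert out.ub[out.column("internal", 1, "R1")] == pytest.approx(42.0)

    def test_irreversible_lower_bound_zero_reversible_negative(self, toy_net):
        from scfba.synthetic import FixtureSpec, default_medium, simulate_expression
        from scfba.expression import reconcile_with_bulk
        from scfba.ras import compute_ras_matrix

        data, _ = simulate_expression(toy_net, FixtureSpec(n_cells=3, dropout_rate=0, seed=1))
        data, _ = reconcile_with_bulk(data)
        model = apply_medium(build_population_model(toy_net, 3), default_medium(n_pop=3))
        caps = compute_flux_capacities(model)
        ras = normalize_ras(compute_ras_matrix(toy_net, data))
        out = apply_ras_bounds(model, caps, ras)
        j_irr = out.column("internal", 1, "GLY1")
        j_rev = out.column("internal", 1, "LDH")
        assert out.lb[j_irr] == 0.0
        assert out.lb[j_rev] == pytest.approx(-out.ub[j_rev])

    def test_bound_sum_identity(self):
        # sum_c U - F = (n_cells - 1) * eps exactly, for any share vector
        n = 6
        net, model = _chain_model(n_cells=n)
        caps = CapacityTable(
            f_forward=pd.Series({"R1": 10.0}),
            f_backward=pd.Series({"R1": 0.0}),
            capacity=pd.Series({"R1": 10.0}),
        )
        rng = np.random.default_rng(0)
        scores = rng.random((1, n)) * 7
        ras = _ras(scores, [f"c{i}" for i in range(n)])
        ras.normalized.index = ["R1"]
        ras.ras.index = ["R1"]
        eps = 1e-3
        out = apply_ras_bounds(model, caps, ras, epsilon=eps)
        total = sum(out.ub[out.column("internal", c, "R1")] for c in range(1, n + 1))
        assert total - 10.0 == pytest.approx((n - 1) * eps, abs=1e-12)

    def test_monotone_in_share(self):
        net, model = _chain_model(n_cells=2)
        caps = CapacityTable(
            f_forward=pd.Series({"R1": 10.0}),
            f_backward=pd.Series({"R1": 0.0}),
            capacity=pd.Series({"R1": 10.0}),
        )
        ubs = []
        for s1 in (1.0, 2.0, 5.0):
            ras = _ras([[s1, 1.0]], ["c1", "c2"])
            ras.normalized.index = ["R1"]
            ras.ras.index = ["R1"]
            out = apply_ras_bounds(model, caps, ras)
            ubs.append(out.ub[out.column("internal", 1, "R1")])
        assert ubs == sorted(ubs)

    def test_epsilon_exceeding_capacity_clamped(self, caplog):
        net, model = _chain_model(n_cells=2)
        caps = CapacityTable(
            f_forward=pd.Series({"R1": 1e-6}),
            f_backward=pd.Series({"R1": 0.0}),
            capacity=pd.Series({"R1": 1e-6}),
        )
        ras = _ras([[1.0, 1.0]], ["c1", "c2"])
        ras.normalized.index = ["R1"]
        ras.ras.index = ["R1"]
        out = apply_ras_bounds(model, caps, ras, epsilon=1e-3)
        j = out.column("internal", 1, "R1")
        assert out.ub[j] >= 1e-3 - 1e-15

    def test_negative_epsilon_rejected(self, toy_net):
        from scfba.synthetic import default_medium

        model = apply_medium(build_population_model(toy_net, 1), default_medium(n_pop=1))
        caps = compute_flux_capacities(model)
        ras = _ras([[1.0]], ["c1"])
        ras.ras.index = ["GLY2"]
        ras.normalized.index = ["GLY2"]
        with pytest.raises(ValueError):
            apply_ras_bounds(model, caps, ras, epsilon=-0.1)


class TestRelaxationMonotonicity:
    def test_epsilon_zero_still_feasible_and_below_default(self, toy_net, het_fixture):
        from scfba.expression import reconcile_with_bulk
        from scfba.ras import compute_ras_matrix
        from scfba.synthetic import default_medium

        data, _ = het_fixture
        data, _ = reconcile_with_bulk(data)
        model = apply_medium(build_population_model(toy_net, data.n_cells),
                             default_medium(n_pop=data.n_cells))
        caps = compute_flux_capacities(model)
        ras = normalize_ras(compute_ras_matrix(toy_net, data))
        at_zero = optimize_population(apply_ras_bounds(model, caps, ras, 0.0))
        at_default = optimize_population(apply_ras_bounds(model, caps, ras, 1e-3))
        assert at_zero.status == "optimal"
        assert at_default.status == "optimal"
        assert at_zero.objective_value <= at_default.objective_value + 1e-9
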