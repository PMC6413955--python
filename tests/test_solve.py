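"""Optimization, per-cell variability, gene deletions, cooperation knockouts."""

import numpy as np
import pytest

from scfba.pipeline import RunConfig, prepare_run, run_pipeline
from scfba.population import MediumSpec, apply_medium, build_population_model
from scfba.solve import (
    cooperation_knockout_ratio,
    optimize_population,
    per_cell_biomass_span,
    single_gene_deletion,
)
from scfba.synthetic import FixtureSpec, default_medium, simulate_expression

from conftest import template_lp_oracle


class TestOptimize:
    def test_two_cell_chain_matches_oracle(self, chain_net):
        # population optimum = total uptake (each step carries what comes in)
        medium = MediumSpec(uptake={"a": 10.0}, n_pop=2)
        model = apply_medium(build_population_model(chain_net, 2), medium)
        result = optimize_population(model)
        oracle = template_lp_oracle(
            chain_net, {"EX_a": (-20, 0), "EX_bio": (0, np.inf)}, "EX_bio"
        )
        assert result.objective_value == pytest.approx(oracle, rel=1e-9)
        assert result.objective_value == pytest.approx(20.0)

    def test_all_uptakes_closed_zero_optimum(self, toy_net):
        medium = MediumSpec(uptake={}, n_pop=2)
        model = apply_medium(build_population_model(toy_net, 2), medium)
        result = optimize_population(model)
        assert result.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_and_bounds_hold(self, toy_net):
        model = apply_medium(build_population_model(toy_net, 3), default_medium(n_pop=3))
        result = optimize_population(model)
        residual = np.abs(model.S @ result.v).max()
        assert residual < 1e-6
        assert (result.v >= model.lb - 1e-6).all()
        assert (result.v <= model.ub + 1e-6).all()

    def test_reproducible_objective(self, toy_net, het_fixture):
        data, _ = het_fixture
        medium = default_medium(n_pop=data.n_cells)
        values = [
            run_pipeline(toy_net, data, medium, RunConfig(mode="scFBA")).solution.objective_value
            for _ in range(2)
        ]
        assert values[0] == pytest.approx(values[1], rel=1e-12)

    def test_atp_objective(self, toy_net):
        model = apply_medium(build_population_model(toy_net, 2), default_medium(n_pop=2))
        result = optimize_population(model, objective="atp", atp_species="atp")
        assert result.status == "optimal"
        assert result.objective_value > 0

    def test_atp_objective_requires_species(self, toy_net):
        model = apply_medium(build_population_model(toy_net, 1), default_medium(n_pop=1))
        with pytest.raises(ValueError, match="atp_species"):
            optimize_population(model, objective="atp")


class TestBiomassSpan:
    def test_single_cell_span_is_total(self, toy_net):
        model = apply_medium(build_population_model(toy_net, 1), default_medium(n_pop=1))
        span = per_cell_biomass_span(model)
        total = span["total"].iloc[0]
        assert span["min"].iloc[0] == pytest.approx(total, rel=1e-6)
        assert span["max"].iloc[0] == pytest.approx(total, rel=1e-6)

    def test_identical_cells_full_span(self, toy_net):
        model = apply_medium(build_population_model(toy_net, 4), default_medium(n_pop=4))
        span = per_cell_biomass_span(model)
        np.testing.assert_allclose(span["min_frac"], 0.0, atol=1e-6)
        np.testing.assert_allclose(span["max_frac"], 1.0, atol=1e-6)


class TestGeneDeletion:
    def test_gene_absent_from_gprs(self, toy_net, het_fixture):
        data, _ = het_fixture
        run = prepare_run(toy_net, data, default_medium(n_pop=data.n_cells),
                          RunConfig(mode="popFBA"))
        report = single_gene_deletion(run.model, run.template, ["not_a_gene"])
        assert report.gr_ratio["not_a_gene"] == 1.0

    def test_essential_gene_zero_ratio(self, toy_net, het_fixture):
        data, _ = het_fixture
        run = prepare_run(toy_net, data, default_medium(n_pop=data.n_cells),
                          RunConfig(mode="popFBA"))
        report = single_gene_deletion(run.model, run.template, ["gZ1"])
        assert report.gr_ratio["gZ1"] == pytest.approx(0.0, abs=1e-9)

    def test_or_redundancy_in_popfba(self, toy_net, het_fixture):
        data, _ = het_fixture
        run = prepare_run(toy_net, data, default_medium(n_pop=data.n_cells),
                          RunConfig(mode="popFBA"))
        report = single_gene_deletion(run.model, run.template, ["gA1"])
        assert report.gr_ratio["gA1"] == 1.0

    def test_silent_isoform_becomes_limiting_in_scfba(self, toy_net, het_fixture):
        # gA2 backs gA1 up in the GPR but is never measured: harmless in the
        # unconstrained population, crippling once scores gate the bounds
        data, _ = het_fixture
        run = prepare_run(toy_net, data, default_medium(n_pop=data.n_cells),
                          RunConfig(mode="scFBA"))
        report = single_gene_deletion(
            run.model, run.template_star, ["gA1"], ras_context=run.ras_context
        )
        assert report.gr_ratio["gA1"] < 0.05

    def test_ratios_in_unit_interval(self, toy_net, het_fixture):
        data, _ = het_fixture
        run = prepare_run(toy_net, data, default_medium(n_pop=data.n_cells),
                          RunConfig(mode="scFBA"))
        report = single_gene_deletion(
            run.model, run.template_star, ras_context=run.ras_context
        )
        assert ((report.gr_ratio >= 0) & (report.gr_ratio <= 1)).all()


class TestCooperationKnockout:
    def test_homogeneous_ratio_is_one(self, toy_net, homog_fixture):
        data, _ = homog_fixture
        run = prepare_run(toy_net, data, default_medium(n_pop=data.n_cells),
                          RunConfig(mode="scFBA"))
        ratio = cooperation_knockout_ratio(run.model)
        assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_heterogeneous_ratio_below_one(self, toy_net, het_fixture):
        data, _ = het_fixture
        run = prepare_run(toy_net, data, default_medium(n_pop=data.n_cells),
                          RunConfig(mode="scFBA"))
        ratio = cooperation_knockout_ratio(run.model)
        assert ratio < 1.0 - 1e-6

    def test_never_exceeds_one(self, toy_net):
        for seed in range(5):
            data, _ = simulate_expression(
                toy_net, FixtureSpec(n_cells=6, dropout_rate=0.2, seed=seed)
            )
            run = prepare_run(toy_net, data, default_medium(n_pop=6), RunConfig(mode="scFBA"))
            ratio = cooperation_knockout_ratio(run.model)
            assert ratio is None or ratio <= 1 + 1e-9

    def test_undefined_when_open_optimum_zero(self, toy_net, homog_fixture):
        data, _ = homog_fixture
        medium = MediumSpec(uptake={}, secretable_to_blood={"lac"},
                            secretable_to_tme={"lac"}, n_pop=data.n_cells)
        run = prepare_run(toy_net, data, medium, RunConfig(mode="scFBA"))
        assert cooperation_knockout_ratio(run.model) is None
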