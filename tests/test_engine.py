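"""Constraint engine: FBA, quadratic flux minimisation, FVA, consistency,
knockouts and energy-cycle certification."""

import numpy as np
import pytest

from conftest import (
    assert_qp_optimal,
    brute_force_blocked,
    brute_force_fva,
    cycle_test_model,
    linear_chain,
    parallel_routes,
)
from rhizoflux import fixtures as fx
from rhizoflux.compose import apply_condition
from rhizoflux.engine import (
    detect_energy_generating_cycles,
    find_blocked_reactions,
    flux_variability,
    minimize_quadratic_flux,
    single_reaction_knockouts,
    solve_fba,
)
from rhizoflux.model import assemble_stoichiometric_matrix


class TestFBA:
    def test_chain_throughput_equals_uptake_bound(self):
        system = assemble_stoichiometric_matrix(linear_chain(2, uptake=10))
        sol = solve_fba(system, "max")
        assert sol.ok
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        assert sol.steady_state_residual <= 1e-6

    def test_forced_demand_above_supply_is_infeasible_not_zero(self):
        model = linear_chain(2, uptake=10)
        model.set_bounds("EX_out", 11.0, 1000.0)
        sol = solve_fba(assemble_stoichiometric_matrix(model), "max")
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_parallel_routes_reach_total_demand(self):
        system = assemble_stoichiometric_matrix(parallel_routes((1, 1), demand=10))
        sol = solve_fba(system, "max")
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        # route split is arbitrary but must sum to the demand
        assert sol.fluxes["P0_0"] + sol.fluxes["P1_0"] == pytest.approx(10.0, abs=1e-8)


class TestQuadraticFluxMinimisation:
    def test_symmetric_parallel_routes_split_evenly(self):
        model = parallel_routes((1, 1))
        model.set_bounds("EX_b", 10.0, 10.0)
        system = assemble_stoichiometric_matrix(model)
        sol = minimize_quadratic_flux(system)
        assert sol.ok
        assert sol.fluxes["P0_0"] == pytest.approx(5.0, abs=1e-6)
        assert sol.fluxes["P1_0"] == pytest.approx(5.0, abs=1e-6)

    def test_route_length_split_matches_kkt_closed_form(self):
        # routes of 2 vs 3 unit reactions forced to carry 10 in total:
        # min 2a^2 + 3b^2 s.t. a + b = 10  ->  a = 6, b = 4
        model = parallel_routes((2, 3))
        system = assemble_stoichiometric_matrix(model)
        sol = minimize_quadratic_flux(system, [("EX_b", 10.0)])
        assert sol.ok
        assert sol.fluxes["P0_0"] == pytest.approx(6.0, abs=1e-6)
        assert sol.fluxes["P1_0"] == pytest.approx(4.0, abs=1e-6)
        assert_qp_optimal(system, {"EX_b": 10.0}, sol)

    def test_closed_exchanges_give_zero_flux_vector(self):
        model = parallel_routes((1, 1))
        model.set_bounds("EX_a", 0.0, 0.0)
        model.set_bounds("EX_b", 0.0, 0.0)
        sol = minimize_quadratic_flux(assemble_stoichiometric_matrix(model))
        assert sol.ok
        assert sol.objective_value == pytest.approx(0.0, abs=1e-10)

    def test_infeasible_fixed_constraints_reported(self):
        system = assemble_stoichiometric_matrix(linear_chain(2, uptake=10))
        sol = minimize_quadratic_flux(system, [("EX_out", 11.0)])
        assert sol.status == "infeasible"

    def test_repeated_solves_agree_per_flux(self, mini_plant):
        night = apply_condition(mini_plant, fx.night_condition())
        system = assemble_stoichiometric_matrix(night)
        fixed = [("BIOMASS", 0.1), ("EX_nh4", -0.015), ("EX_no3", 0.0)]
        a = minimize_quadratic_flux(system, fixed)
        b = minimize_quadratic_flux(system, fixed)
        assert a.ok and b.ok
        for rid in a.fluxes:
            assert abs(a.fluxes[rid] - b.fluxes[rid]) < 1e-6

    def test_fixture_qp_passes_lp_optimality_certificate(self, mini_plant):
        night = apply_condition(mini_plant, fx.night_condition())
        system = assemble_stoichiometric_matrix(night)
        fixed = {"BIOMASS": 0.1, "EX_nh4": 0.0, "EX_no3": -0.015}
        sol = minimize_quadratic_flux(system, list(fixed.items()))
        assert sol.ok
        assert_qp_optimal(system, fixed, sol, tol=1e-5)

    def test_qp_on_fba_optimal_face_preserves_fba_objective(self, mini_plant):
        # the nesting property: fixing growth at the FBA optimum and
        # minimising Σv² keeps that optimum exactly
        day = apply_condition(mini_plant, fx.day_condition())
        system = assemble_stoichiometric_matrix(day)
        fba = solve_fba(system, "max")
        qp = minimize_quadratic_flux(system, [("BIOMASS", fba.objective_value)])
        assert qp.ok
        assert qp.fluxes["BIOMASS"] == pytest.approx(fba.objective_value, abs=1e-8)
        assert qp.steady_state_residual <= 1e-6


class TestFluxVariability:
    def test_chain_at_full_objective_is_degenerate(self):
        system = assemble_stoichiometric_matrix(linear_chain(2, uptake=10))
        ranges = flux_variability(system, 1.0)
        for rid in ("R1", "R2", "EX_out"):
            lo, hi = ranges[rid]
            assert lo == pytest.approx(10.0, abs=1e-7)
            assert hi == pytest.approx(10.0, abs=1e-7)

    def test_parallel_routes_full_range(self):
        system = assemble_stoichiometric_matrix(parallel_routes((1, 1), demand=10))
        ranges = flux_variability(system, 1.0)
        for rid in ("P0_0", "P1_0"):
            assert ranges[rid][0] == pytest.approx(0.0, abs=1e-7)
            assert ranges[rid][1] == pytest.approx(10.0, abs=1e-7)

    def test_matches_two_lp_brute_force_on_random_networks(self):
        for seed in (3, 7):
            model = fx.build_random_consistent_model(25, seed)
            system = assemble_stoichiometric_matrix(model)
            got = flux_variability(system)  # no objective -> plain ranges
            want = brute_force_fva(system)
            for rid in got:
                assert got[rid][0] == pytest.approx(want[rid][0], abs=1e-6)
                assert got[rid][1] == pytest.approx(want[rid][1], abs=1e-6)

    def test_fraction_must_be_unit_interval(self, mini_plant):
        system = assemble_stoichiometric_matrix(mini_plant)
        with pytest.raises(ValueError):
            flux_variability(system, 1.5)


class TestBlockedReactions:
    def test_dead_end_production_is_blocked(self):
        model = linear_chain(2)
        from rhizoflux.model import Metabolite, Reaction

        model.add_metabolite(Metabolite("dead_c", "c", formula={"C": 1}, charge=0))
        model.add_reaction(Reaction("TO_DEAD", {"m1_c": -1.0, "dead_c": 1.0}, 0, 1000))
        assert find_blocked_reactions(model) == {"TO_DEAD"}

    def test_connected_chain_has_no_blocked_reactions(self):
        assert find_blocked_reactions(linear_chain(3)) == set()

    def test_matches_fva_oracle_on_random_networks(self):
        for seed in range(8):
            model = fx.build_random_consistent_model(30, seed)
            assert find_blocked_reactions(model) == brute_force_blocked(model)


class TestKnockouts:
    def test_every_chain_reaction_is_essential(self):
        res = single_reaction_knockouts(linear_chain(3))
        assert res.essential == set(res.knockout_objective)

    def test_duplicated_route_reactions_are_not_essential(self):
        res = single_reaction_knockouts(parallel_routes((1, 1), demand=10))
        assert "P0_0" not in res.essential
        assert "P1_0" not in res.essential
        assert "EX_a" in res.essential

    def test_knockout_objective_never_exceeds_wild_type(self, mini_plant):
        # zeroing a reaction only restricts the feasible set when zero was
        # admissible; a forced demand (maintenance lb > 0) is *relaxed* by
        # its knockout, so monotonicity applies to the zero-admitting rest
        cond = fx.day_condition().stacked(fx.nitrogen_condition(1000, 0))
        work = mini_plant.copy()
        cond.apply(work)
        res = single_reaction_knockouts(mini_plant, cond)
        for rid, obj in res.knockout_objective.items():
            rxn = work.reactions[rid]
            if obj is not None and rxn.lower_bound <= 0.0 <= rxn.upper_bound:
                assert obj <= res.wild_type_objective + 1e-6

    def test_maltose_exporter_essential_only_at_night(self, mini_plant):
        n_src = fx.nitrogen_condition(1000, 0)
        night = single_reaction_knockouts(mini_plant, fx.night_condition().stacked(n_src))
        day = single_reaction_knockouts(mini_plant, fx.day_condition().stacked(n_src))
        assert "MEX" in night.essential
        assert "MEX" not in day.essential
        # photon-dependent machinery: essential by day, irrelevant by night
        for rid in ("PSII", "CALVIN", "PHOTOPHOS"):
            assert rid in day.essential
            assert rid not in night.essential

    def test_requires_viable_wild_type(self, mini_plant):
        dead = fx.night_condition().stacked(fx.nitrogen_condition(0, 0))
        with pytest.raises(RuntimeError):
            single_reaction_knockouts(mini_plant, dead)


class TestEnergyCycles:
    def test_curated_fixtures_are_cycle_free(self, mini_plant, mini_rhizobium):
        for model in (mini_plant, mini_rhizobium):
            sol = detect_energy_generating_cycles(model, "MAINT")
            assert sol.ok
            assert sol.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_flipped_transporter_creates_energy_cycle(self):
        ok = detect_energy_generating_cycles(cycle_test_model(flipped=False), "MAINT")
        assert ok.objective_value == pytest.approx(0.0, abs=1e-9)
        bad = detect_energy_generating_cycles(cycle_test_model(flipped=True), "MAINT")
        assert bad.objective_value > 1.0
        # the returned flux vector localises the loop
        active = {r for r, v in bad.fluxes.items() if abs(v) > 1e-6}
        assert {"T_x", "PUMP"} <= active

    def test_loop_free_model_has_zero_optimum(self):
        model = linear_chain(2)
        from rhizoflux.model import Metabolite, Reaction

        for mid in ("atp_c", "adp_c"):
            model.add_metabolite(Metabolite(mid, "c", formula={}, charge=0))
        model.add_reaction(Reaction("MAINT", {"atp_c": -1.0, "adp_c": 1.0},
                                    0, 1000, kind="maintenance"))
        model.add_reaction(Reaction("GEN", {"m0_c": -1.0, "m1_c": 1.0,
                                            "adp_c": -1.0, "atp_c": 1.0}, 0, 1000))
        sol = detect_energy_generating_cycles(model, "MAINT")
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
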