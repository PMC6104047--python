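"""Tissue replication, linkers, biomass merging and symbiont attachment."""

import pytest

from rhizoflux import fixtures as fx
from rhizoflux.compose import (
    ExchangeLink,
    LinkerSpec,
    SymbiosisSpec,
    add_linker_reactions,
    apply_condition,
    attach_symbiont,
    merge_biomass,
    replicate_into_tissues,
)
from rhizoflux.engine import minimize_quadratic_flux, solve_fba
from rhizoflux.model import (
    ModelIntegrityError,
    assemble_stoichiometric_matrix,
    check_reaction_balance,
    validate_model,
)


class TestReplication:
    def test_counts_and_prefixes(self, mini_plant):
        combined = replicate_into_tissues(mini_plant, ["shoot", "root"])
        assert len(combined.reactions) == 2 * len(mini_plant.reactions)
        assert len(combined.metabolites) == 2 * len(mini_plant.metabolites)
        assert "shoot_BIOMASS" in combined.reactions
        assert "root_MEX" in combined.reactions
        assert combined.reactions["root_MEX"].gpr == mini_plant.reactions["MEX"].gpr

    def test_validation_survives_replication(self, mini_plant):
        combined = replicate_into_tissues(mini_plant, ["shoot", "root"])
        report = validate_model(combined)
        assert report.imbalanced == []

    def test_isolated_tissue_keeps_source_optimum(self, mini_plant):
        day = apply_condition(mini_plant, fx.day_condition())
        base = solve_fba(assemble_stoichiometric_matrix(day), "max")
        combined = replicate_into_tissues(day, ["shoot", "root"])
        combined.objective = {"shoot_BIOMASS": 1.0}
        sol = solve_fba(assemble_stoichiometric_matrix(combined), "max",
                        "shoot_BIOMASS")
        assert sol.objective_value == pytest.approx(base.objective_value, abs=1e-6)

    def test_distinct_tissue_names_required(self, mini_plant):
        with pytest.raises(ValueError):
            replicate_into_tissues(mini_plant, ["shoot", "shoot"])


class TestLinkers:
    def test_sucrose_linker_enables_root_growth_on_shoot_carbon(self, spec, mini_plant):
        combined = replicate_into_tissues(mini_plant, ["shoot", "root"])
        merge_biomass(combined, 0.5)
        conditioned = apply_condition(combined, fx.two_tissue_day_condition(spec))
        fx.two_tissue_nitrogen_condition(1000.0).apply(conditioned)
        # no linkers: the dark root has no carbon source; it cannot even
        # pay its maintenance ATP, so the system is outright infeasible
        no_link = solve_fba(assemble_stoichiometric_matrix(conditioned), "max")
        assert not no_link.ok
        # with the linkers, shoot-fixed carbon reaches the root
        linked = add_linker_reactions(conditioned.copy(), fx.default_linkers())
        sol = solve_fba(assemble_stoichiometric_matrix(linked), "max")
        assert sol.objective_value > 0.1

    def test_duplicate_linker_rejected(self, mini_plant):
        combined = replicate_into_tissues(mini_plant, ["shoot", "root"])
        link = LinkerSpec("suc_c", "shoot", "root")
        add_linker_reactions(combined, [link])
        with pytest.raises(ModelIntegrityError, match="duplicate"):
            add_linker_reactions(combined, [link])

    def test_linker_metabolite_must_exist(self, mini_plant):
        combined = replicate_into_tissues(mini_plant, ["shoot", "root"])
        with pytest.raises(ModelIntegrityError, match="ghost"):
            add_linker_reactions(combined, [LinkerSpec("ghost_c", "shoot", "root")])

    def test_generated_linkers_pass_balance(self, two_tissue):
        for rid, rxn in two_tissue.reactions.items():
            if rid.startswith("TL_"):
                report = check_reaction_balance(rxn, two_tissue.metabolites)
                assert report.balanced, rid


class TestBiomassMerging:
    def test_symmetric_fractions_force_equal_tissue_fluxes(self, two_tissue):
        system = assemble_stoichiometric_matrix(two_tissue)
        sol = minimize_quadratic_flux(system, [("BIOMASS_combined", 0.1)])
        assert sol.ok
        assert sol.fluxes["shoot_BIOMASS"] == pytest.approx(0.05, abs=1e-7)
        assert sol.fluxes["root_BIOMASS"] == pytest.approx(0.05, abs=1e-7)

    def test_asymmetric_fraction_coefficients(self, mini_plant):
        combined = replicate_into_tissues(mini_plant, ["shoot", "root"])
        merge_biomass(combined, 0.67)
        stoich = combined.reactions["BIOMASS_combined"].stoichiometry
        assert stoich["shoot_biomass_unit"] == pytest.approx(-0.67)
        assert stoich["root_biomass_unit"] == pytest.approx(-0.33)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 1.5, -0.1])
    def test_degenerate_fractions_rejected(self, mini_plant, alpha):
        combined = replicate_into_tissues(mini_plant, ["shoot", "root"])
        with pytest.raises(ValueError):
            merge_biomass(combined, alpha)


class TestSymbiontAttachment:
    def test_symbiotic_system_grows_without_external_nitrogen(self, symbiotic_day_no_n):
        sol = solve_fba(assemble_stoichiometric_matrix(symbiotic_day_no_n), "max")
        assert sol.ok
        assert sol.objective_value > 0.1

    def test_no_oxygen_means_no_fixation_and_no_growth(self, symbiotic_day_no_n):
        dark = symbiotic_day_no_n.copy()
        dark.set_bounds("TS_o2_b", 0.0, 0.0)
        sol = solve_fba(assemble_stoichiometric_matrix(dark), "max")
        # without oxygen the bacteroid cannot pay its maintenance ATP:
        # no fixation, and the coupled system cannot sustain itself at all
        assert (not sol.ok) or sol.objective_value <= 1e-8

    def test_abundant_ammonium_growth_not_above_plain_plant(
            self, plant_day_no_n, symbiotic_day_no_n):
        rich_plant = plant_day_no_n.copy()
        rich_plant.set_bounds("root_EX_nh4", -1000.0, 0.0)
        rich_sym = symbiotic_day_no_n.copy()
        rich_sym.set_bounds("root_EX_nh4", -1000.0, 0.0)
        plant = solve_fba(assemble_stoichiometric_matrix(rich_plant), "max")
        sym = solve_fba(assemble_stoichiometric_matrix(rich_sym), "max")
        assert sym.objective_value <= plant.objective_value + 1e-6
        assert sym.objective_value < plant.objective_value  # maintenance cost

    def test_closed_coupling_leaves_plant_optimum_unchanged(
            self, spec, two_tissue, mini_rhizobium):
        coupling = fx.default_symbiosis_spec(spec)
        closed = SymbiosisSpec(
            links=[ExchangeLink(l.symbiont_metabolite, l.plant_metabolite, 0.0, 0.0,
                                l.plant_cofactors) for l in coupling.links],
            f=coupling.f, maintenance_atp=0.0, maintenance_reaction="MAINT",
        )
        combined = attach_symbiont(two_tissue, mini_rhizobium, closed)
        day = fx.two_tissue_day_condition(spec)
        a = solve_fba(assemble_stoichiometric_matrix(
            apply_condition(two_tissue, day)), "max")
        b = solve_fba(assemble_stoichiometric_matrix(
            apply_condition(combined, day)), "max")
        assert b.objective_value == pytest.approx(a.objective_value, abs=1e-6)

    def test_missing_exchange_metabolite_is_an_error(self, two_tissue, mini_rhizobium):
        bad = SymbiosisSpec(links=[ExchangeLink("ghost_b", "root_mal_c")])
        with pytest.raises(ModelIntegrityError, match="ghost"):
            attach_symbiont(two_tissue, mini_rhizobium, bad)

    def test_coupling_transports_pass_balance(self, symbiotic):
        for rid, rxn in symbiotic.reactions.items():
            if rid.startswith("TS_"):
                report = check_reaction_balance(rxn, symbiotic.metabolites)
                assert report.balanced, rid

    def test_symbiont_bounds_scaled_by_mass_fraction(self, spec, symbiotic,
                                                     mini_rhizobium):
        nif = symbiotic.reactions["sym_NIF"]
        assert nif.upper_bound == pytest.approx(
            mini_rhizobium.reactions["NIF"].upper_bound * spec.symbiont_fraction)
        maint = symbiotic.reactions["sym_MAINT"]
        assert maint.lower_bound == pytest.approx(
            spec.symbiont_maintenance_atp * spec.symbiont_fraction)


class TestApplyCondition:
    def test_returns_copy_and_applies_bounds(self, mini_plant):
        night = apply_condition(mini_plant, fx.night_condition())
        assert night is not mini_plant
        assert night.reactions["EX_photon"].upper_bound == 0.0
        assert night.reactions["EX_photon"].lower_bound == 0.0
        assert mini_plant.reactions["EX_photon"].lower_bound < 0.0

    def test_stacked_day_plus_nitrogen(self, mini_plant):
        cond = fx.day_condition().stacked(fx.nitrogen_condition(5.0, 0.0))
        work = apply_condition(mini_plant, cond)
        assert work.reactions["EX_photon"].lower_bound < 0.0
        assert work.reactions["EX_nh4"].lower_bound == -5.0
        assert work.reactions["EX_no3"].lower_bound == 0.0
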