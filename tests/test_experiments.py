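"""Scan experiments: nitrogen sources, symbiosis growth, oxygen
availability, essentiality screens and carbon conversion."""

import numpy as np
import pytest

from rhizoflux import fixtures as fx
from rhizoflux.compose import apply_condition
from rhizoflux.experiments import (
    carbon_conversion_efficiency,
    day_night_essentiality,
    knockout_variant,
    minimum_oxygen_requirement,
    nitrogen_source_scan,
    oxygen_availability_scan,
    symbiosis_growth_comparison,
)
from rhizoflux.engine import solve_fba
from rhizoflux.model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    assemble_stoichiometric_matrix,
)
from rhizoflux.io import ConditionSpec


@pytest.fixture(scope="module")
def nitrogen_scan(spec, mini_plant):
    night = apply_condition(mini_plant, fx.night_condition())
    return nitrogen_source_scan(
        night, 0.1 * spec.nitrogen_demand_per_gram,
        np.linspace(0.0, 1.0, 11), growth=0.1, markers=fx.PLANT_SCAN_MARKERS,
    )


class TestNitrogenScan:
    def test_all_points_feasible_and_steady(self, nitrogen_scan):
        for rec in nitrogen_scan.records:
            assert rec["feasible"]
            assert rec["residual"] <= 1e-6
            assert rec["growth"] == pytest.approx(0.1)

    def test_net_acid_export_tracks_nitrogen_charge(self, spec, nitrogen_scan):
        # net acid export = H+ export - HCO3- export; charge conservation
        # ties it to the signed charge of the nitrogen uptake
        total_n = 0.1 * spec.nitrogen_demand_per_gram
        for lam, rec in zip(nitrogen_scan.grid, nitrogen_scan.records):
            net = rec["fluxes"]["proton_exchange"] - rec["fluxes"]["hco3_exchange"]
            expected = (2.0 * lam - 1.0) * total_n
            assert net == pytest.approx(expected, abs=1e-6)

    def test_pure_ammonium_exports_acid(self, nitrogen_scan):
        rec = nitrogen_scan.records[-1]  # lambda = 1
        net = rec["fluxes"]["proton_exchange"] - rec["fluxes"]["hco3_exchange"]
        assert net > 1e-4

    def test_pure_nitrate_imports_acid_and_exports_bicarbonate(self, nitrogen_scan):
        rec = nitrogen_scan.records[0]  # lambda = 0
        net = rec["fluxes"]["proton_exchange"] - rec["fluxes"]["hco3_exchange"]
        assert net < -1e-4
        assert rec["fluxes"]["hco3_exchange"] > 0.0

    def test_equimolar_nutrition_is_acid_balanced(self, nitrogen_scan):
        rec = nitrogen_scan.records[5]  # lambda = 0.5
        net = rec["fluxes"]["proton_exchange"] - rec["fluxes"]["hco3_exchange"]
        assert abs(net) < 1e-6

    def test_starch_demand_drops_with_ammonium(self, nitrogen_scan):
        starch = [-r["fluxes"]["starch_exchange"] for r in nitrogen_scan.records]
        assert starch[-1] < starch[0]
        assert all(b <= a + 1e-9 for a, b in zip(starch, starch[1:]))

    def test_tca_falls_and_atpase_rises_with_ammonium(self, nitrogen_scan):
        tca = [r["fluxes"]["tca"] for r in nitrogen_scan.records]
        atpase = [r["fluxes"]["mito_atpase"] for r in nitrogen_scan.records]
        assert tca[-1] < tca[0]
        assert atpase[-1] > atpase[0]

    def test_infeasible_points_flagged_and_scan_continues(self, spec, mini_plant):
        night = apply_condition(mini_plant, fx.night_condition())
        # demanding more growth than nitrogen allows at low total N
        scan = nitrogen_source_scan(night, 1e-6, np.linspace(0, 1, 3), growth=0.1)
        assert all(not rec["feasible"] for rec in scan.records)
        assert all("fluxes" not in rec for rec in scan.records)


class TestSymbiosisComparison:
    def test_growth_curves_cross_exactly_once(self, plant_day_no_n, symbiotic_day_no_n):
        grid = np.linspace(0.0, 0.5, 9)
        df = symbiosis_growth_comparison(plant_day_no_n, symbiotic_day_no_n, grid)
        diff = df["growth_symbiotic"] - df["growth_plant"]
        signs = np.sign(diff[np.abs(diff) > 1e-9])
        crossings = int(np.sum(np.abs(np.diff(signs)) > 0))
        assert crossings == 1

    def test_zero_nitrogen_endpoint(self, plant_day_no_n, symbiotic_day_no_n):
        df = symbiosis_growth_comparison(plant_day_no_n, symbiotic_day_no_n, [0.0])
        assert df.loc[0, "growth_plant"] == pytest.approx(0.0, abs=1e-8)
        assert df.loc[0, "growth_symbiotic"] > 0.1

    def test_rich_nitrogen_endpoint(self, plant_day_no_n, symbiotic_day_no_n):
        df = symbiosis_growth_comparison(plant_day_no_n, symbiotic_day_no_n, [0.5])
        assert df.loc[0, "growth_symbiotic"] < df.loc[0, "growth_plant"]


@pytest.fixture(scope="module")
def oxygen_scans(symbiotic_day_no_n):
    wt = oxygen_availability_scan(symbiotic_day_no_n, 0.8,
                                  markers=fx.SYMBIONT_SCAN_MARKERS, n_points=12)
    ko = oxygen_availability_scan(symbiotic_day_no_n, 0.8,
                                  knockouts=("sym_ALADH",),
                                  markers=fx.SYMBIONT_SCAN_MARKERS, n_points=12)
    return wt, ko


class TestOxygenScan:
    def test_growth_fixed_and_residuals_small(self, oxygen_scans):
        wt, _ = oxygen_scans
        target = wt.meta["fixed_growth"]
        assert target == pytest.approx(0.8 * wt.meta["max_growth"])
        for rec in wt.records:
            if rec["feasible"]:
                assert rec["residual"] <= 1e-6
                assert rec["growth"] == pytest.approx(target)

    def test_feasibility_monotone_in_oxygen(self, oxygen_scans):
        for scan in oxygen_scans:
            flags = [rec["feasible"] for rec in scan.records]
            first = flags.index(True)
            assert all(flags[first:])
            assert not any(flags[:first])

    def test_wild_type_exports_nitrogen_only_as_alanine(self, oxygen_scans):
        wt, _ = oxygen_scans
        for o2, rec in wt.feasible_points():
            assert abs(rec["fluxes"]["ammonia"]) < 1e-6
            assert rec["fluxes"]["alanine"] < -1e-3  # symbiont -> plant

    def test_malate_to_succinate_switch_with_oxygen(self, oxygen_scans):
        wt, _ = oxygen_scans
        feasible = wt.feasible_points()
        low, high = feasible[0][1], feasible[-1][1]
        assert low["fluxes"]["malate"] > 1e-3
        assert low["fluxes"]["succinate"] == pytest.approx(0.0, abs=1e-6)
        assert high["fluxes"]["succinate"] > 1e-3

    def test_amino_acid_cycling_shrinks_with_oxygen(self, oxygen_scans):
        wt, _ = oxygen_scans
        feasible = wt.feasible_points()
        assert feasible[0][1]["fluxes"]["glutamate"] > \
            feasible[-1][1]["fluxes"]["glutamate"] + 1e-6

    def test_knockout_exports_ammonia_but_still_cycles_alanine(self, oxygen_scans):
        _, ko = oxygen_scans
        o2_min, rec = ko.feasible_points()[0]
        assert rec["fluxes"]["ammonia"] < -1e-3  # symbiont -> plant
        # alanine still leaves, matched by glutamate import (pure cycling)
        assert rec["fluxes"]["alanine"] < -1e-3
        assert rec["fluxes"]["alanine"] == pytest.approx(
            -rec["fluxes"]["glutamate"], abs=1e-6)

    def test_knockout_needs_strictly_more_oxygen(self, symbiotic_day_no_n):
        wt = minimum_oxygen_requirement(symbiotic_day_no_n, 0.8)
        ko = minimum_oxygen_requirement(symbiotic_day_no_n, 0.8,
                                        knockouts=("sym_ALADH",))
        assert ko > wt + 1e-6


class TestKnockoutVariant:
    def test_empty_list_is_identity(self, mini_plant):
        variant = knockout_variant(mini_plant, [])
        assert variant.id == mini_plant.id
        for rid in mini_plant.reactions:
            assert variant.reactions[rid].lower_bound == \
                mini_plant.reactions[rid].lower_bound

    def test_nitrogenase_knockout_abolishes_zero_n_growth(self, symbiotic_day_no_n):
        variant = knockout_variant(symbiotic_day_no_n, ["sym_NIF"])
        sol = solve_fba(assemble_stoichiometric_matrix(variant), "max")
        assert sol.objective_value == pytest.approx(0.0, abs=1e-8)


class TestDayNightEssentiality:
    def test_condition_specific_sets(self, mini_plant):
        n_src = fx.nitrogen_condition(1000, 0)
        res = day_night_essentiality(
            mini_plant, fx.day_condition().stacked(n_src),
            fx.night_condition().stacked(n_src))
        day, night = res["day"].essential, res["night"].essential
        assert "STARCH_DEG" in night - day  # starch degradation: night only
        assert "MEX" in night - day
        assert "CALVIN" in day - night      # carbon fixation: day only
        assert "PSII" in day - night
        assert res["shared"] == day & night
        assert len(res["shared"]) <= min(len(day), len(night))
        assert res["night"].n_essential_transporters >= 1


class TestCarbonConversion:
    def test_free_carbon_skeleton_converts_completely(self):
        # biomass needs only the carbon skeleton and no ATP: nothing must
        # be respired, so the efficiency is exactly 1
        m = MetabolicModel(id="freeC")
        m.add_compartment("c")
        m.add_metabolite(Metabolite("glc_c", "c", formula={"C": 6, "H": 12, "O": 6},
                                    charge=0))
        m.add_reaction(Reaction("EX_glc", {"glc_c": -1.0}, -1000, 0, kind="exchange"))
        m.add_reaction(Reaction("BIOMASS", {"glc_c": -1.0}, 0, 1000, kind="biomass"))
        m.objective = {"BIOMASS": 1.0}
        res = carbon_conversion_efficiency(
            m, ConditionSpec("none"), growth=0.1, carbon_exchange="EX_glc")
        assert res.efficiency == pytest.approx(1.0, abs=1e-9)
        assert abs(res.carbon_balance_residual) < 1e-6

    def test_atp_cost_matches_closed_form_yield(self):
        # biomass needs 1 glucose + a ATP; respiring one glucose yields y
        # ATP: efficiency = y / (y + a)  (per-carbon costs cancel)
        a, y = 10.0, 30.0
        m = MetabolicModel(id="atpcost")
        m.add_compartment("c")
        for mid, formula in [("glc_c", {"C": 6, "H": 12, "O": 6}),
                             ("co2_c", {"C": 1, "O": 2}), ("o2_c", {"O": 2}),
                             ("atp_c", {}), ("adp_c", {})]:
            m.add_metabolite(Metabolite(mid, "c", formula=formula, charge=0))
        m.add_reaction(Reaction("EX_glc", {"glc_c": -1.0}, -1000, 0, kind="exchange"))
        m.add_reaction(Reaction("EX_co2", {"co2_c": -1.0}, 0, 1000, kind="exchange"))
        m.add_reaction(Reaction("EX_o2", {"o2_c": -1.0}, -1000, 0, kind="exchange"))
        m.add_reaction(Reaction("RESP", {"glc_c": -1.0, "o2_c": -6.0, "adp_c": -y,
                                         "co2_c": 6.0, "atp_c": y}, 0, 1000))
        m.add_reaction(Reaction("BIOMASS", {"glc_c": -1.0, "atp_c": -a,
                                            "adp_c": a}, 0, 1000, kind="biomass"))
        m.objective = {"BIOMASS": 1.0}
        res = carbon_conversion_efficiency(
            m, ConditionSpec("none"), growth=0.5, carbon_exchange="EX_glc")
        assert res.efficiency == pytest.approx(y / (y + a), abs=1e-9)
        assert abs(res.carbon_balance_residual) < 1e-6

    def test_ammonium_beats_nitrate(self, mini_plant):
        night = fx.night_condition()
        on_nh4 = carbon_conversion_efficiency(
            mini_plant, night.stacked(fx.nitrogen_condition(1000, 0)))
        on_no3 = carbon_conversion_efficiency(
            mini_plant, night.stacked(fx.nitrogen_condition(0, 1000)))
        assert 0.0 < on_no3.efficiency < on_nh4.efficiency < 1.0
        for res in (on_nh4, on_no3):
            assert abs(res.carbon_balance_residual) < 1e-6
            assert res.respired_fraction == pytest.approx(1 - res.efficiency)

    def test_missing_carbon_formula_raises(self, mini_plant):
        broken = mini_plant.copy()
        broken.metabolites["starch_p"].formula = None
        with pytest.raises((ValueError, RuntimeError), match="formula"):
            carbon_conversion_efficiency(
                broken, fx.night_condition().stacked(fx.nitrogen_condition(1000, 0)))
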