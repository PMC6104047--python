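"""Curated synthetic mini-models and random consistent networks.

These fixtures emulate, at toy scale, the structure of a
compartmentalised legume metabolic network and its nitrogen-fixing
bacteroid partner, so that every pipeline stage (validation, FBA/QP,
consistency, FASTCORE, composition, scans) is exercisable without any
external download:

* :func:`build_mini_plant` -- a ~55-reaction plant cell over external,
  cytosol, plastid and mitochondrion compartments: photon capture and a
  lumped Calvin cycle, starch synthesis/degradation with maltose export
  through the plastid envelope, lumped glycolysis and TCA, oxidative
  phosphorylation at a configurable P/O ratio, nitrate reduction
  (8 e⁻ per N) and ammonium assimilation with explicit proton/charge
  bookkeeping, amino-acid synthesis, HCO3⁻/H⁺ exchanges, biomass and ATP
  maintenance.  Every internal reaction is balanced for C, H, N, O, P
  and charge.
* :func:`build_mini_rhizobium` -- a ~20-reaction bacteroid: nitrogenase
  at the classical 16 ATP / 8 e⁻ per N₂ stoichiometry, malate and
  succinate TCA entry points differing by exactly one reductant,
  reversible pyruvate carboxylase, alanine dehydrogenase,
  glutamate-pyruvate transaminase, succinyl-CoA-synthase ATP yield, and
  oxygen-capped oxidative phosphorylation.
* :func:`build_random_consistent_model` -- seeded random single
  compartment networks with guaranteed-balanced template reactions and
  ≥80 % flux-consistent reactions, for oracle tests.

Both curated fixtures self-check at construction time: zero internal
mass/charge imbalances and a zero optimum for the closed-exchange
energy-cycle certification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compose import (
    ExchangeLink,
    LinkerSpec,
    SymbiosisSpec,
    add_linker_reactions,
    attach_symbiont,
    merge_biomass,
    replicate_into_tissues,
)
from .engine import detect_energy_generating_cycles
from .io import ConditionSpec
from .model import MetabolicModel, Metabolite, Reaction, parse_formula, validate_model

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "build_mini_plant",
    "build_mini_rhizobium",
    "build_random_consistent_model",
    "build_two_tissue_plant",
    "build_symbiotic_system",
    "default_symbiosis_spec",
    "default_linkers",
    "day_condition",
    "night_condition",
    "nitrogen_condition",
    "two_tissue_day_condition",
    "two_tissue_nitrogen_condition",
    "default_expression",
    "PLANT_SCAN_MARKERS",
    "SYMBIONT_SCAN_MARKERS",
]


class FixtureError(RuntimeError):
    pass


@dataclass
class FixtureSpec:
    """Tunable parameters of the curated fixtures.

    ``p_o_ratio`` is ATP per NADH oxidised (fixture behaviour is robust
    over [1.5, 3]); nitrogenase uses the classical 8 electrons per N₂
    (the only electron count that closes the H/charge books with one H₂
    per N₂) and a configurable ATP cost.  Biomass coefficients are
    mmol per g dry weight; biomass consumes only neutral species plus an
    internally balanced ATP hydrolysis so the growth drain is charge- and
    free-proton-neutral.
    """

    p_o_ratio: float = 2.5
    nitrogenase_atp: float = 16.0
    biomass_glucose: float = 0.25
    biomass_alanine: float = 0.10
    biomass_glutamine: float = 0.025
    biomass_atp: float = 6.0
    plant_maintenance_atp: float = 1.0
    symbiont_maintenance_atp: float = 30.0
    photon_cap: float = 100.0
    symbiont_fraction: float = 0.02
    symbiont_o2_cap: float = 5.0
    shoot_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 1.0 <= self.p_o_ratio <= 4.0:
            raise FixtureError(f"implausible P/O ratio {self.p_o_ratio}")
        if self.nitrogenase_atp < 4.0:
            raise FixtureError("nitrogenase ATP cost must cover proton bookkeeping (>= 4)")

    @property
    def nitrogen_demand_per_gram(self) -> float:
        """mmol N consumed per gram of biomass (alanine + glutamine)."""
        return self.biomass_alanine + 2.0 * self.biomass_glutamine


# species formula/charge table (shared by both fixtures)
_SPECIES: dict[str, tuple[str, float]] = {
    "photon": ("", 0),
    "co2": ("CO2", 0),
    "hco3": ("CHO3", -1),
    "o2": ("O2", 0),
    "h2o": ("H2O", 0),
    "h": ("H", 1),
    "nh4": ("H4N", 1),
    "nh3": ("H3N", 0),
    "no3": ("NO3", -1),
    "n2": ("N2", 0),
    "h2": ("H2", 0),
    "pi": ("HO4P", -2),
    "atp": ("C10H12N5O13P3", -4),
    "adp": ("C10H12N5O10P2", -3),
    "nad": ("C21H26N7O14P2", -1),
    "nadh": ("C21H27N7O14P2", -2),
    "nadp": ("C21H25N7O17P3", -3),
    "nadph": ("C21H26N7O17P3", -4),
    "glc": ("C6H12O6", 0),
    "g6p": ("C6H11O9P", -2),
    "pyr": ("C3H3O3", -1),
    "akg": ("C5H4O5", -2),
    "glu": ("C5H8NO4", -1),
    "ala": ("C3H7NO2", 0),
    "gln": ("C5H10N2O3", 0),
    "mal": ("C4H4O5", -2),
    "succ": ("C4H4O4", -2),
    "oaa": ("C4H2O5", -2),
    "starch": ("C6H10O5", 0),
    "maltose": ("C12H22O11", 0),
    "suc": ("C12H22O11", 0),
}


def _met(model: MetabolicModel, base: str, comp: str) -> str:
    mid = f"{base}_{comp}"
    if mid not in model.metabolites:
        formula, charge = _SPECIES[base]
        model.add_metabolite(
            Metabolite(mid, comp, name=base, formula=parse_formula(formula), charge=charge)
        )
    return mid


def _self_check(model: MetabolicModel, demand: str) -> None:
    report = validate_model(model)
    if report.imbalanced:
        raise FixtureError(f"{model.id}: imbalanced reactions {report.imbalanced}")
    if report.unverifiable:
        raise FixtureError(f"{model.id}: unverifiable reactions {report.unverifiable}")
    cycle = detect_energy_generating_cycles(model, demand)
    if not cycle.ok or cycle.objective_value > 1e-6:
        raise FixtureError(
            f"{model.id}: energy-generating cycle detected "
            f"(max closed-exchange demand {cycle.objective_value})"
        )


def build_mini_plant(spec: FixtureSpec | None = None, self_check: bool = True) -> MetabolicModel:
    """The compartmentalised mini-plant (see module docstring).

    Default bounds leave every nutrient route open (photon up to the
    spec's cap, ammonium, nitrate, and a reversible starch storage
    exchange); apply :func:`day_condition` / :func:`night_condition` /
    :func:`nitrogen_condition` to pin a regime.
    """
    spec = spec or FixtureSpec()
    r = spec.p_o_ratio
    m = MetabolicModel(id="mini_plant")
    for cid, name in [("e", "external"), ("c", "cytosol"),
                      ("p", "plastid"), ("m", "mitochondrion")]:
        m.add_compartment(cid, name)

    def met(base: str, comp: str) -> str:
        return _met(m, base, comp)

    def rxn(rid: str, stoich: dict[str, float], lb: float, ub: float,
            kind: str = "internal", gpr: str | None = "auto", name: str = "") -> None:
        if gpr == "auto":
            gpr = "g_" + rid.lower() if kind in ("internal", "transport") else ""
        m.add_reaction(Reaction(rid, stoich, lb, ub, gpr or "", kind, name))

    # exchanges (species -> nothing; uptake is negative flux)
    for base, comp, lb, ub in [
        ("photon", "e", -spec.photon_cap, 0.0),
        ("co2", "e", -1000.0, 1000.0),
        ("o2", "e", -1000.0, 1000.0),
        ("h2o", "e", -1000.0, 1000.0),
        ("h", "e", -1000.0, 1000.0),
        ("nh4", "e", -1000.0, 0.0),
        ("no3", "e", -1000.0, 0.0),
        ("hco3", "e", -1000.0, 1000.0),
        ("starch", "p", -1000.0, 1000.0),  # storage pool: draw at night, fill by day
        ("mal", "c", 0.0, 1000.0),         # root exudation
        ("succ", "c", 0.0, 1000.0),
    ]:
        rxn(f"EX_{base}", {met(base, comp): -1.0}, lb, ub, kind="exchange", gpr=None)

    # membrane transports (uniports; charge translocation is explicit)
    transports = [
        ("T_photon", {met("photon", "e"): -1, met("photon", "p"): 1}, 0, 1000),
        ("T_co2", {met("co2", "e"): -1, met("co2", "c"): 1}, -1000, 1000),
        ("T_co2_p", {met("co2", "c"): -1, met("co2", "p"): 1}, -1000, 1000),
        ("T_co2_m", {met("co2", "c"): -1, met("co2", "m"): 1}, -1000, 1000),
        ("T_o2", {met("o2", "e"): -1, met("o2", "c"): 1}, -1000, 1000),
        ("T_o2_p", {met("o2", "p"): -1, met("o2", "c"): 1}, -1000, 1000),
        ("T_o2_m", {met("o2", "c"): -1, met("o2", "m"): 1}, -1000, 1000),
        ("T_h2o", {met("h2o", "e"): -1, met("h2o", "c"): 1}, -1000, 1000),
        ("T_h2o_p", {met("h2o", "c"): -1, met("h2o", "p"): 1}, -1000, 1000),
        ("T_h2o_m", {met("h2o", "c"): -1, met("h2o", "m"): 1}, -1000, 1000),
        ("T_h", {met("h", "c"): -1, met("h", "e"): 1}, -1000, 1000),
        ("T_h_m", {met("h", "c"): -1, met("h", "m"): 1}, -1000, 1000),
        ("T_nh4", {met("nh4", "e"): -1, met("nh4", "c"): 1}, 0, 1000),
        ("T_no3", {met("no3", "e"): -1, met("no3", "c"): 1}, 0, 1000),
        ("T_hco3", {met("hco3", "c"): -1, met("hco3", "e"): 1}, -1000, 1000),
        # the maltose exporter in the plastid envelope
        ("MEX", {met("maltose", "p"): -1, met("maltose", "c"): 1}, 0, 1000),
        ("T_g6p", {met("g6p", "p"): -1, met("g6p", "c"): 1}, -1000, 1000),
        ("T_pi_p", {met("pi", "c"): -1, met("pi", "p"): 1}, -1000, 1000),
        ("T_pyr", {met("pyr", "c"): -1, met("pyr", "m"): 1}, -1000, 1000),
        ("T_akg", {met("akg", "m"): -1, met("akg", "c"): 1}, 0, 1000),
        ("T_atp", {met("atp", "m"): -1, met("adp", "c"): -1,
                   met("atp", "c"): 1, met("adp", "m"): 1}, 0, 1000),
        ("T_pi_m", {met("pi", "c"): -1, met("pi", "m"): 1}, -1000, 1000),
        ("SHUTTLE_NADH", {met("nadh", "c"): -1, met("nad", "m"): -1,
                          met("nad", "c"): 1, met("nadh", "m"): 1}, -1000, 1000),
    ]
    for rid, stoich, lb, ub in transports:
        rxn(rid, stoich, lb, ub, kind="transport")

    # plastid: light reactions, photophosphorylation, Calvin lump, starch
    rxn("PSII", {met("photon", "p"): -8, met("h2o", "p"): -2, met("nadp", "p"): -2,
                 met("o2", "p"): 1, met("nadph", "p"): 2, met("h", "p"): 2}, 0, 1000)
    rxn("PHOTOPHOS", {met("photon", "p"): -4, met("adp", "p"): -1, met("pi", "p"): -1,
                      met("h", "p"): -1, met("atp", "p"): 1, met("h2o", "p"): 1}, 0, 1000)
    rxn("CALVIN", {met("co2", "p"): -6, met("nadph", "p"): -12, met("atp", "p"): -18,
                   met("h2o", "p"): -11, met("g6p", "p"): 1, met("nadp", "p"): 12,
                   met("adp", "p"): 18, met("pi", "p"): 17, met("h", "p"): 6}, 0, 1000)
    rxn("STARCH_SYN", {met("g6p", "p"): -1, met("atp", "p"): -1, met("h2o", "p"): -1,
                       met("starch", "p"): 1, met("adp", "p"): 1, met("pi", "p"): 2,
                       met("h", "p"): 1}, 0, 1000)
    rxn("STARCH_DEG", {met("starch", "p"): -2, met("h2o", "p"): -1,
                       met("maltose", "p"): 1}, 0, 1000)

    # cytosol: sugar handling, glycolysis, carbonic anhydrase, N assimilation
    rxn("MALTASE", {met("maltose", "c"): -1, met("h2o", "c"): -1, met("glc", "c"): 2}, 0, 1000)
    rxn("HXK", {met("glc", "c"): -1, met("atp", "c"): -1,
                met("g6p", "c"): 1, met("adp", "c"): 1, met("h", "c"): 1}, 0, 1000)
    rxn("GLYC", {met("g6p", "c"): -1, met("adp", "c"): -3, met("pi", "c"): -2,
                 met("nad", "c"): -2, met("pyr", "c"): 2, met("atp", "c"): 3,
                 met("nadh", "c"): 2, met("h2o", "c"): 2, met("h", "c"): 1}, 0, 1000)
    rxn("CA", {met("co2", "c"): -1, met("h2o", "c"): -1,
               met("hco3", "c"): 1, met("h", "c"): 1}, -1000, 1000)
    rxn("NR", {met("no3", "c"): -1, met("nadh", "c"): -4, met("h", "c"): -6,
               met("nh4", "c"): 1, met("nad", "c"): 4, met("h2o", "c"): 3}, 0, 1000)
    rxn("GS_GOGAT", {met("nh4", "c"): -1, met("akg", "c"): -1, met("nadh", "c"): -1,
                     met("atp", "c"): -1, met("glu", "c"): 1, met("nad", "c"): 1,
                     met("adp", "c"): 1, met("pi", "c"): 1}, 0, 1000)
    rxn("GDH", {met("glu", "c"): -1, met("nad", "c"): -1, met("h2o", "c"): -1,
                met("akg", "c"): 1, met("nh4", "c"): 1, met("nadh", "c"): 1,
                met("h", "c"): 1}, -1000, 1000)
    rxn("GLN_SYN", {met("glu", "c"): -1, met("nh4", "c"): -1, met("atp", "c"): -1,
                    met("gln", "c"): 1, met("adp", "c"): 1, met("pi", "c"): 1,
                    met("h", "c"): 1}, 0, 1000)
    rxn("ALT", {met("glu", "c"): -1, met("pyr", "c"): -1,
                met("akg", "c"): 1, met("ala", "c"): 1}, -1000, 1000)
    rxn("SUC_SYN", {met("g6p", "c"): -2, met("h2o", "c"): -1,
                    met("suc", "c"): 1, met("pi", "c"): 2}, 0, 1000)
    rxn("INV", {met("suc", "c"): -1, met("h2o", "c"): -1, met("glc", "c"): 2}, 0, 1000)
    rxn("MAL_SYN", {met("pyr", "c"): -1, met("co2", "c"): -1, met("nadh", "c"): -1,
                    met("mal", "c"): 1, met("nad", "c"): 1}, 0, 1000)
    rxn("SUCC_SYN", {met("mal", "c"): -1, met("nadh", "c"): -1, met("h", "c"): -1,
                     met("succ", "c"): 1, met("nad", "c"): 1, met("h2o", "c"): 1}, 0, 1000)

    # mitochondrion: pyruvate oxidation, 2-oxoglutarate supply, respiration
    rxn("PDH_TCA", {met("pyr", "m"): -1, met("nad", "m"): -5, met("adp", "m"): -1,
                    met("pi", "m"): -1, met("h2o", "m"): -2, met("co2", "m"): 3,
                    met("nadh", "m"): 5, met("atp", "m"): 1, met("h", "m"): 3}, 0, 1000)
    rxn("AKG_SYN", {met("pyr", "m"): -2, met("atp", "m"): -1, met("nad", "m"): -2,
                    met("h2o", "m"): -2, met("akg", "m"): 1, met("co2", "m"): 1,
                    met("nadh", "m"): 2, met("adp", "m"): 1, met("pi", "m"): 1,
                    met("h", "m"): 3}, 0, 1000)
    rxn("OXPHOS", {met("nadh", "m"): -1, met("o2", "m"): -0.5, met("adp", "m"): -r,
                   met("pi", "m"): -r, met("h", "m"): -(1 + r), met("nad", "m"): 1,
                   met("atp", "m"): r, met("h2o", "m"): 1 + r}, 0, 1000)

    # maintenance and growth
    rxn("MAINT", {met("atp", "c"): -1, met("h2o", "c"): -1, met("adp", "c"): 1,
                  met("pi", "c"): 1, met("h", "c"): 1},
        spec.plant_maintenance_atp, 1000, kind="maintenance", gpr=None)
    a = spec.biomass_atp
    rxn("BIOMASS", {met("glc", "c"): -spec.biomass_glucose,
                    met("ala", "c"): -spec.biomass_alanine,
                    met("gln", "c"): -spec.biomass_glutamine,
                    met("atp", "c"): -a, met("h2o", "c"): -a,
                    met("adp", "c"): a, met("pi", "c"): a, met("h", "c"): a},
        0, 1000, kind="biomass", gpr=None)
    m.objective = {"BIOMASS": 1.0}
    m.check_integrity()
    if self_check:
        _self_check(m, "MAINT")
    return m


def build_mini_rhizobium(spec: FixtureSpec | None = None,
                         self_check: bool = True) -> MetabolicModel:
    """The bacteroid mini-model (see module docstring).

    The standalone model exchanges dicarboxylates, glutamate, alanine,
    ammonia, gases and protons across its boundary; in the symbiotic
    configuration the coupled exchanges are replaced by plant transports.
    """
    spec = spec or FixtureSpec()
    r = spec.p_o_ratio
    A = spec.nitrogenase_atp
    m = MetabolicModel(id="mini_rhizobium")
    m.add_compartment("b", "bacteroid")

    def met(base: str) -> str:
        return _met(m, base, "b")

    def rxn(rid, stoich, lb, ub, kind="internal", gpr=""):
        m.add_reaction(Reaction(rid, stoich, lb, ub, gpr, kind))

    for base, lb, ub in [
        ("mal", -1000, 0), ("succ", -1000, 0), ("glu", -1000, 0),
        ("ala", 0, 1000), ("nh3", 0, 1000), ("o2", -1000, 0),
        ("n2", -1000, 0), ("h2", 0, 1000), ("co2", -1000, 1000),
        ("h2o", -1000, 1000), ("h", -1000, 1000),
    ]:
        rxn(f"EX_{base}", {met(base): -1.0}, lb, ub, kind="exchange")

    # nitrogenase: N2 + 8 H+ + 8 e- + A ATP -> 2 NH3 + H2 (classical)
    rxn("NIF", {met("n2"): -1, met("nadh"): -4, met("atp"): -A, met("h2o"): -A,
                met("nh3"): 2, met("h2"): 1, met("nad"): 4, met("adp"): A,
                met("pi"): A, met("h"): A - 4}, 0, 1000, gpr="g_nifH")
    rxn("ME", {met("mal"): -1, met("nad"): -1, met("pyr"): 1, met("co2"): 1,
               met("nadh"): 1}, 0, 1000, gpr="g_dme")
    rxn("MDH", {met("mal"): -1, met("nad"): -1, met("oaa"): 1, met("nadh"): 1,
                met("h"): 1}, -1000, 1000, gpr="g_mdh")
    # succinate entry: exactly one reductant more than malate entry
    rxn("SDH_FUM", {met("succ"): -1, met("nad"): -1, met("h2o"): -1,
                    met("mal"): 1, met("nadh"): 1, met("h"): 1}, 0, 1000, gpr="g_sdh")
    rxn("PYC", {met("pyr"): -1, met("co2"): -1, met("h2o"): -1, met("atp"): -1,
                met("oaa"): 1, met("adp"): 1, met("pi"): 1, met("h"): 2},
        -1000, 1000, gpr="g_pyc")
    rxn("ALADH", {met("pyr"): -1, met("nh4"): -1, met("nadh"): -1, met("h"): -1,
                  met("ala"): 1, met("nad"): 1, met("h2o"): 1}, 0, 1000, gpr="g_alaDH")
    rxn("NH4EQ", {met("nh3"): -1, met("h"): -1, met("nh4"): 1}, -1000, 1000)
    rxn("GPT", {met("glu"): -1, met("pyr"): -1, met("akg"): 1, met("ala"): 1},
        -1000, 1000, gpr="g_gpt")
    # 2-oxoglutarate oxidation with succinyl-CoA-synthase ATP yield
    rxn("AKGDH_SCS", {met("akg"): -1, met("nad"): -1, met("adp"): -1, met("pi"): -1,
                      met("succ"): 1, met("co2"): 1, met("nadh"): 1, met("atp"): 1},
        0, 1000, gpr="g_sucCD")
    rxn("PDH_TCA", {met("pyr"): -1, met("nad"): -5, met("adp"): -1, met("pi"): -1,
                    met("h2o"): -2, met("co2"): 3, met("nadh"): 5, met("atp"): 1,
                    met("h"): 3}, 0, 1000, gpr="g_pdh")
    rxn("OXPHOS", {met("nadh"): -1, met("o2"): -0.5, met("adp"): -r, met("pi"): -r,
                   met("h"): -(1 + r), met("nad"): 1, met("atp"): r,
                   met("h2o"): 1 + r}, 0, 1000, gpr="g_cox")
    rxn("MAINT", {met("atp"): -1, met("h2o"): -1, met("adp"): 1, met("pi"): 1,
                  met("h"): 1}, 0.0, 1000, kind="maintenance")
    m.check_integrity()
    if self_check:
        _self_check(m, "MAINT")
    return m


# ---------------------------------------------------------------------------
# conditions
# ---------------------------------------------------------------------------


def day_condition(spec: FixtureSpec | None = None) -> ConditionSpec:
    """Photon uptake enabled, starch accumulation only."""
    spec = spec or FixtureSpec()
    return ConditionSpec("day", {
        "EX_photon": (-spec.photon_cap, 0.0),
        "EX_starch": (0.0, 1000.0),
    })


def night_condition() -> ConditionSpec:
    """No photon; starch drawn from storage as energy and carbon source.

    Dicarboxylate exudation is closed: it is a daytime, symbiosis-serving
    route, and leaving it open would let charged carbon exports dominate
    the proton/bicarbonate bookkeeping the nitrogen scans probe."""
    return ConditionSpec("night", {
        "EX_photon": (0.0, 0.0),
        "EX_starch": (-1000.0, 0.0),
        "EX_mal": (0.0, 0.0),
        "EX_succ": (0.0, 0.0),
    })


def nitrogen_condition(nh4: float, no3: float, name: str | None = None) -> ConditionSpec:
    """Cap ammonium/nitrate availability (mmol·gDW⁻¹·day⁻¹ uptake)."""
    return ConditionSpec(
        name or f"N(nh4={nh4:g},no3={no3:g})",
        {"EX_nh4": (-float(nh4), 0.0), "EX_no3": (-float(no3), 0.0)},
    )


def two_tissue_day_condition(spec: FixtureSpec | None = None) -> ConditionSpec:
    """Day regime for the shoot/root model: light reaches only the shoot,
    soil nitrogen and exudation only the root."""
    spec = spec or FixtureSpec()
    return ConditionSpec("tt_day", {
        "shoot_EX_photon": (-spec.photon_cap, 0.0),
        "root_EX_photon": (0.0, 0.0),
        "shoot_EX_starch": (0.0, 1000.0),
        "root_EX_starch": (0.0, 1000.0),
        "shoot_EX_nh4": (0.0, 0.0),
        "shoot_EX_no3": (0.0, 0.0),
        "shoot_EX_mal": (0.0, 0.0),
        "shoot_EX_succ": (0.0, 0.0),
    })


def two_tissue_nitrogen_condition(nh4: float, no3: float = 0.0) -> ConditionSpec:
    return ConditionSpec(
        f"tt_N(nh4={nh4:g},no3={no3:g})",
        {"root_EX_nh4": (-float(nh4), 0.0), "root_EX_no3": (-float(no3), 0.0)},
    )


# ---------------------------------------------------------------------------
# expression and composition defaults
# ---------------------------------------------------------------------------

_ROOT_SILENT_GENES = ("g_psii", "g_photophos", "g_calvin", "g_t_photon",
                      "g_t_o2_p", "g_t_co2_p")


def default_expression(model: MetabolicModel | None = None):
    """Two-tissue expression table: photosynthesis genes silent in root."""
    import pandas as pd

    from .fastcore import ExpressionTable

    model = model or build_mini_plant(self_check=False)
    genes = sorted(model.genes())
    data = pd.DataFrame({
        "shoot": [10.0] * len(genes),
        "root": [0.0 if g in _ROOT_SILENT_GENES else 10.0 for g in genes],
    }, index=pd.Index(genes, name="gene_id"))
    return ExpressionTable(data)


def default_linkers() -> list[LinkerSpec]:
    """Inter-tissue transporters: sucrose down, nitrogen carriers up."""
    return [
        LinkerSpec("suc_c", "shoot", "root"),
        LinkerSpec("nh4_c", "root", "shoot"),
        LinkerSpec("ala_c", "root", "shoot"),
        LinkerSpec("glu_c", "root", "shoot"),
    ]


def build_two_tissue_plant(spec: FixtureSpec | None = None) -> MetabolicModel:
    """Replicate the mini-plant into shoot and root, link the tissues and
    merge the biomasses (fixtures pin a symmetric split by default)."""
    spec = spec or FixtureSpec()
    base = build_mini_plant(spec, self_check=False)
    combined = replicate_into_tissues(base, ["shoot", "root"])
    add_linker_reactions(combined, default_linkers())
    merge_biomass(combined, spec.shoot_fraction)
    return combined


def default_symbiosis_spec(spec: FixtureSpec | None = None) -> SymbiosisSpec:
    """Literature-motivated coupling: dicarboxylates, glutamate and oxygen
    flow to the bacteroid, alanine and ammonia (arriving protonated as
    ammonium) return to the root.  Oxygen carries the sole active cap."""
    spec = spec or FixtureSpec()
    return SymbiosisSpec(
        links=[
            ExchangeLink("mal_b", "root_mal_c", 0.0, 1000.0),
            ExchangeLink("succ_b", "root_succ_c", 0.0, 1000.0),
            ExchangeLink("glu_b", "root_glu_c", 0.0, 1000.0),
            ExchangeLink("o2_b", "root_o2_c", 0.0, spec.symbiont_o2_cap),
            ExchangeLink("ala_b", "root_ala_c", -1000.0, 0.0),
            ExchangeLink("nh3_b", "root_nh4_c", -1000.0, 0.0,
                         plant_cofactors={"root_h_c": 1.0}),
        ],
        f=spec.symbiont_fraction,
        maintenance_atp=spec.symbiont_maintenance_atp,
        maintenance_reaction="MAINT",
    )


def build_symbiotic_system(
    spec: FixtureSpec | None = None,
) -> tuple[MetabolicModel, MetabolicModel]:
    """(two-tissue plant, two-tissue plant + bacteroid), both unconditioned."""
    spec = spec or FixtureSpec()
    plant = build_two_tissue_plant(spec)
    symbiotic = attach_symbiont(
        plant, build_mini_rhizobium(spec, self_check=False), default_symbiosis_spec(spec)
    )
    return plant, symbiotic


#: Marker reactions reported by the nitrogen-source scan on the mini-plant.
PLANT_SCAN_MARKERS = {
    "starch_exchange": "EX_starch",
    "tca": "PDH_TCA",
    "mito_atpase": "OXPHOS",
    "proton_exchange": "EX_h",
    "hco3_exchange": "EX_hco3",
}

#: Marker reactions reported by the oxygen scan on the symbiotic model
#: (positive flux = plant → symbiont).
SYMBIONT_SCAN_MARKERS = {
    "malate": "TS_mal_b",
    "succinate": "TS_succ_b",
    "glutamate": "TS_glu_b",
    "alanine": "TS_ala_b",
    "ammonia": "TS_nh3_b",
    "oxygen": "TS_o2_b",
}


# ---------------------------------------------------------------------------
# random consistent networks (oracle substrate)
# ---------------------------------------------------------------------------


def build_random_consistent_model(n_reactions: int, seed: int) -> MetabolicModel:
    """A seeded random single-compartment network, ≥80 % flux-consistent.

    Metabolites carry pure-carbon formulas; reactions are built only from
    balanced templates (equal-carbon conversion, merge A+B→C with
    C = A + B carbons) so the whole model passes validation.  A small
    fraction of deliberate dead-end reactions provides blocked reactions
    for oracle tests.  Reproducible: same seed, identical model.
    """
    if n_reactions < 4:
        raise ValueError("need at least 4 reactions")
    if n_reactions > 60:
        raise ValueError("random fixture capped at 60 reactions")
    rng = np.random.default_rng(seed)
    m = MetabolicModel(id=f"random_{n_reactions}_{seed}")
    m.add_compartment("c", "cytosol")

    n_backbone = max(3, n_reactions // 3)

    def add_met(carbon: int) -> str:
        mid = f"m{len(m.metabolites):03d}"
        m.add_metabolite(Metabolite(mid, "c", formula={"C": float(carbon)}, charge=0))
        return mid

    backbone = [add_met(1) for _ in range(n_backbone)]
    reactions: list[Reaction] = []

    def add(rid, stoich, lb, ub, kind="internal"):
        reactions.append(Reaction(rid, stoich, lb, ub, kind=kind))

    add("EX_src", {backbone[0]: -1.0}, -1000, 0, kind="exchange")
    add("EX_snk", {backbone[-1]: -1.0}, 0, 1000, kind="exchange")
    for i in range(n_backbone - 1):
        rev = rng.random() < 0.3
        add(f"C{i:03d}", {backbone[i]: -1.0, backbone[i + 1]: 1.0},
            -1000 if rev else 0, 1000)

    budget = n_reactions - len(reactions)
    n_dead = max(1, int(round(0.1 * n_reactions)))
    n_extra = budget - n_dead
    k = 0
    while n_extra > 0:
        kind = rng.choice(["conv", "merge"])
        if kind == "conv" or n_extra < 2:
            i, j = sorted(rng.choice(n_backbone, size=2, replace=False))
            rev = rng.random() < 0.3
            add(f"X{k:03d}", {backbone[i]: -1.0, backbone[j]: 1.0},
                -1000 if rev else 0, 1000)
            n_extra -= 1
        else:
            i, j = rng.choice(n_backbone, size=2, replace=True)
            c2 = add_met(2)
            add(f"M{k:03d}", {backbone[i]: -1.0, backbone[j]: -1.0
                              if i != j else -2.0, c2: 1.0}
                if i != j else {backbone[i]: -2.0, c2: 1.0}, 0, 1000)
            add(f"EX_{c2}", {c2: -1.0}, 0, 1000, kind="exchange")
            n_extra -= 2
        k += 1
    for d in range(n_dead):
        i = int(rng.integers(n_backbone))
        dead = add_met(1)
        add(f"D{d:03d}", {backbone[i]: -1.0, dead: 1.0}, 0, 1000)

    for rxn in reactions:
        m.add_reaction(rxn)
    m.check_integrity()
    return m
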