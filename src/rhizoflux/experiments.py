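"""In-silico experiments: nitrogen-source and oxygen-availability scans,
symbiosis growth comparison, day/night essentiality and starch-carbon
conversion efficiency.

Each scan fixes a small number of target fluxes per grid point (growth
rate, nutrient uptakes, symbiont oxygen) and reports the *unique*
quadratic-flux-minimal distribution at that point, the modelling
translation of maximally efficient enzyme usage.  Infeasible grid points
are flagged and carry no fluxes; the scan continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    EssentialityResult,
    minimize_quadratic_flux,
    single_reaction_knockouts,
    solve_fba,
)
from .io import ConditionSpec
from .model import MetabolicModel, assemble_stoichiometric_matrix
from .solve import lp

__all__ = [
    "ScanResult",
    "nitrogen_source_scan",
    "symbiosis_growth_comparison",
    "oxygen_availability_scan",
    "knockout_variant",
    "day_night_essentiality",
    "carbon_conversion_efficiency",
    "CarbonConversionResult",
]


@dataclass
class ScanResult:
    """A table of parameter values × selected reaction fluxes.

    One record per grid point: feasibility flag, growth rate, objective
    (Σv² for QP scans) and the marker fluxes.  The grid is strictly
    monotone; infeasible points carry no fluxes.
    """

    parameter: str
    grid: list[float]
    records: list[dict]
    markers: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        diffs = np.diff(self.grid)
        if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("scan grid must be strictly monotone")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for value, rec in zip(self.grid, self.records):
            row = {self.parameter: value, "feasible": rec["feasible"],
                   "growth": rec.get("growth", float("nan")),
                   "objective": rec.get("objective", float("nan"))}
            for label in self.markers:
                row[label] = rec.get("fluxes", {}).get(label, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)

    def feasible_points(self) -> list[tuple[float, dict]]:
        return [(v, r) for v, r in zip(self.grid, self.records) if r["feasible"]]


def _growth_reaction(model: MetabolicModel, growth_reaction: str | None) -> str:
    if growth_reaction is not None:
        return growth_reaction
    if len(model.objective) == 1:
        return next(iter(model.objective))
    raise ValueError("growth reaction ambiguous; pass growth_reaction explicitly")


def _qp_point(system, fixed, markers) -> dict:
    sol = minimize_quadratic_flux(system, fixed)
    if not sol.ok:
        return {"feasible": False}
    return {
        "feasible": True,
        "objective": sol.objective_value,
        "residual": sol.steady_state_residual,
        "fluxes": {label: sol.fluxes[rid] for label, rid in markers.items()},
        "all_fluxes": sol.fluxes,
    }


def nitrogen_source_scan(
    model: MetabolicModel,
    total_n_flux: float,
    ammonium_fractions: np.ndarray | None = None,
    growth: float = 0.1,
    markers: dict[str, str] | None = None,
    growth_reaction: str | None = None,
    ammonium_exchange: str = "EX_nh4",
    nitrate_exchange: str = "EX_no3",
) -> ScanResult:
    """Scan ammonium-vs-nitrate composition at fixed total nitrogen.

    At each ammonium fraction λ the ammonium uptake is fixed to λ·total
    and the nitrate uptake to (1−λ)·total (uptake = negative flux), the
    growth rate is fixed (default 0.1 g·gDW⁻¹·day⁻¹), and the
    quadratic-flux-minimal distribution is recorded.  The model should
    already carry the desired regime (typically night).
    """
    lambdas = (np.linspace(0.0, 1.0, 21) if ammonium_fractions is None
               else np.asarray(ammonium_fractions, dtype=float))
    markers = markers or {}
    biomass = _growth_reaction(model, growth_reaction)
    system = assemble_stoichiometric_matrix(model)
    records = []
    for lam in lambdas:
        fixed = [
            (biomass, growth),
            (ammonium_exchange, -lam * total_n_flux),
            (nitrate_exchange, -(1.0 - lam) * total_n_flux),
        ]
        rec = _qp_point(system, fixed, markers)
        if rec["feasible"]:
            rec["growth"] = growth
        records.append(rec)
    return ScanResult("ammonium_fraction", list(lambdas), records, markers,
                      meta={"total_n_flux": total_n_flux, "growth": growth})


def symbiosis_growth_comparison(
    plant_model: MetabolicModel,
    symbiotic_model: MetabolicModel,
    ammonium_grid: np.ndarray,
    ammonium_exchange: str = "root_EX_nh4",
) -> pd.DataFrame:
    """Maximal growth with and without the nitrogen-fixing symbiont over
    an external ammonium availability grid (plain FBA per point)."""
    rows = []
    for amount in np.asarray(ammonium_grid, dtype=float):
        cond = ConditionSpec(f"nh4={amount:g}",
                             {ammonium_exchange: (-amount, 0.0)})
        growths = {}
        for label, model in (("plant", plant_model), ("symbiotic", symbiotic_model)):
            work = model.copy()
            cond.apply(work)
            sol = solve_fba(assemble_stoichiometric_matrix(work), sense="max")
            growths[label] = sol.objective_value if sol.ok else 0.0
        rows.append({"ammonium": amount, "growth_plant": growths["plant"],
                     "growth_symbiotic": growths["symbiotic"]})
    return pd.DataFrame(rows)


def _min_feasible_flux(system, fixed: list[tuple[str, float]], rid: str) -> float:
    """Smallest attainable flux through ``rid`` given the fixed targets.

    The attainable set is the projection of a polytope, hence an
    interval: its lower end is a single LP.
    """
    lb = system.lb.copy()
    ub = system.ub.copy()
    for fid, value in fixed:
        j = system.reaction_position(fid)
        lb[j] = ub[j] = value
    c = np.zeros(system.n_reactions)
    c[system.reaction_position(rid)] = 1.0
    res = lp(c, system.S, np.zeros(system.n_metabolites), lb, ub)
    if res.status != "optimal":
        raise RuntimeError(f"no feasible point at the fixed targets ({res.status})")
    return float(res.x[system.reaction_position(rid)])


def oxygen_availability_scan(
    symbiotic_model: MetabolicModel,
    growth_fraction: float = 0.8,
    o2_grid: np.ndarray | None = None,
    knockouts: tuple[str, ...] = (),
    o2_reaction: str = "TS_o2_b",
    markers: dict[str, str] | None = None,
    growth_reaction: str | None = None,
    n_points: int = 50,
) -> ScanResult:
    """Vary bacteroid oxygen uptake at fixed plant growth.

    The maximal growth rate is determined first on the *wild-type* model
    (same oxygen-cap configuration); growth is then fixed as an equality
    at ``growth_fraction`` × max.  Per oxygen value the bacteroid oxygen
    transport is fixed and the QP-minimal exchange fluxes recorded.  The
    default grid spans 0 → 2× the wild-type minimum feasible oxygen in
    ``n_points`` even steps.
    """
    markers = markers or {}
    biomass = _growth_reaction(symbiotic_model, growth_reaction)
    wt_system = assemble_stoichiometric_matrix(symbiotic_model)
    wt_max = solve_fba(wt_system, sense="max", objective=biomass)
    if not wt_max.ok or wt_max.objective_value <= 0:
        raise RuntimeError(f"wild-type maximal growth not positive: {wt_max.status}")
    target = growth_fraction * wt_max.objective_value

    if o2_grid is None:
        o2_min = _min_feasible_flux(wt_system, [(biomass, target)], o2_reaction)
        o2_grid = np.linspace(0.0, 2.0 * o2_min, n_points)
    o2_grid = np.asarray(o2_grid, dtype=float)

    variant = knockout_variant(symbiotic_model, list(knockouts))
    system = assemble_stoichiometric_matrix(variant)
    records = []
    for o2 in o2_grid:
        rec = _qp_point(system, [(biomass, target), (o2_reaction, o2)], markers)
        if rec["feasible"]:
            rec["growth"] = target
        records.append(rec)
    return ScanResult("oxygen_uptake", list(o2_grid), records, markers,
                      meta={"max_growth": wt_max.objective_value,
                            "fixed_growth": target,
                            "knockouts": list(knockouts)})


def minimum_oxygen_requirement(
    symbiotic_model: MetabolicModel,
    growth_fraction: float = 0.8,
    knockouts: tuple[str, ...] = (),
    o2_reaction: str = "TS_o2_b",
    growth_reaction: str | None = None,
) -> float:
    """Smallest bacteroid oxygen uptake sustaining the fixed growth.

    Growth is fixed at ``growth_fraction`` × the *wild-type* maximum (so
    knockout variants are held to the same demand); the attainable oxygen
    set is an interval and its lower end is one LP.
    """
    biomass = _growth_reaction(symbiotic_model, growth_reaction)
    wt_system = assemble_stoichiometric_matrix(symbiotic_model)
    wt_max = solve_fba(wt_system, sense="max", objective=biomass)
    if not wt_max.ok or wt_max.objective_value <= 0:
        raise RuntimeError(f"wild-type maximal growth not positive: {wt_max.status}")
    target = growth_fraction * wt_max.objective_value
    variant = knockout_variant(symbiotic_model, list(knockouts))
    system = assemble_stoichiometric_matrix(variant)
    return _min_feasible_flux(system, [(biomass, target)], o2_reaction)


def knockout_variant(model: MetabolicModel, reaction_ids: list[str]) -> MetabolicModel:
    """A copy with the listed reactions forced to zero flux."""
    variant = model.copy()
    variant.knock_out(*reaction_ids)
    if reaction_ids:
        variant.id = model.id + "_ko_" + "+".join(reaction_ids)
    return variant


def day_night_essentiality(
    model: MetabolicModel,
    day: ConditionSpec,
    night: ConditionSpec,
    objective: str | None = None,
) -> dict:
    """Single-reaction knockout screens under both light regimes.

    Returns per-condition :class:`EssentialityResult` plus the shared
    essential set (the intersection).
    """
    results: dict[str, EssentialityResult | set] = {}
    for label, cond in (("day", day), ("night", night)):
        results[label] = single_reaction_knockouts(model, cond, objective=objective)
    results["shared"] = results["day"].essential & results["night"].essential
    return results


@dataclass
class CarbonConversionResult:
    """Outcome of the starch-carbon conversion computation."""

    efficiency: float
    respired_fraction: float
    carbon_in: float
    carbon_to_biomass: float
    carbon_balance_residual: float
    growth: float
    fluxes: dict[str, float]


def carbon_conversion_efficiency(
    model: MetabolicModel,
    condition: ConditionSpec,
    growth: float = 0.1,
    carbon_exchange: str = "EX_starch",
    growth_reaction: str | None = None,
    include_maintenance: bool = False,
) -> CarbonConversionResult:
    """Maximal fraction of imported starch carbon convertible to biomass.

    At the given condition (night + a nitrogen source) the growth rate is
    fixed, the carbon import through ``carbon_exchange`` is minimised by
    LP, and the unique QP flux vector at that minimum is used to verify
    atom conservation: carbon in = carbon to biomass + carbon exported,
    within 1e-6.  Considering only energy and redox requirements of
    biomass formation, maintenance demands are excluded by default.
    """
    work = model.copy()
    condition.apply(work)
    if not include_maintenance:
        for rid in work.reactions_of_kind("maintenance"):
            work.set_bounds(rid, 0.0, work.reactions[rid].upper_bound)
    biomass = _growth_reaction(work, growth_reaction)
    system = assemble_stoichiometric_matrix(work)

    def carbon_of(mid: str) -> float:
        met = work.metabolites[mid]
        if met.formula is None:
            raise ValueError(f"metabolite {mid} lacks a formula; carbon count unknown")
        return float(met.formula.get("C", 0.0))

    # theoretical maximum: minimal carbon import at the fixed growth
    j = system.reaction_position(carbon_exchange)
    lb = system.lb.copy()
    ub = system.ub.copy()
    jb = system.reaction_position(biomass)
    lb[jb] = ub[jb] = growth
    c = np.zeros(system.n_reactions)
    c[j] = -1.0  # uptake is negative: maximising flux minimises import
    res = lp(c, system.S, np.zeros(system.n_metabolites), lb, ub)
    if res.status != "optimal":
        raise RuntimeError(f"carbon minimisation {res.status} at growth {growth}")
    min_uptake = float(res.x[j])  # negative

    sol = minimize_quadratic_flux(
        system, [(biomass, growth), (carbon_exchange, min_uptake)]
    )
    if not sol.ok:
        raise RuntimeError(f"QP at minimal carbon import ended {sol.status}")

    source_species = next(iter(work.reactions[carbon_exchange].stoichiometry))
    carbon_in = -min_uptake * carbon_of(source_species)
    # net carbon drained per unit growth (cofactor pairs like ATP/ADP cancel)
    biomass_carbon_per_unit = -sum(
        coeff * carbon_of(mid)
        for mid, coeff in work.reactions[biomass].stoichiometry.items()
    )
    carbon_to_biomass = growth * biomass_carbon_per_unit

    # atom conservation: all exchange carbon + biomass carbon must close
    balance = 0.0
    for rid in work.exchanges():
        species = next(iter(work.reactions[rid].stoichiometry))
        balance += sol.fluxes[rid] * carbon_of(species)  # export positive
    balance += carbon_to_biomass
    # imports enter with negative sign, so the closed balance is zero
    if carbon_in <= 0:
        raise RuntimeError("no carbon imported through the carbon exchange")
    efficiency = carbon_to_biomass / carbon_in
    return CarbonConversionResult(
        efficiency=efficiency,
        respired_fraction=1.0 - efficiency,
        carbon_in=carbon_in,
        carbon_to_biomass=carbon_to_biomass,
        carbon_balance_residual=float(balance),
        growth=growth,
        fluxes=sol.fluxes,
    )
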