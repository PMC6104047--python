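"""Shared test fixtures and oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from rhizoflux import fixtures as fx
from rhizoflux.compose import apply_condition
from rhizoflux.model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    assemble_stoichiometric_matrix,
)
from rhizoflux.solve import lp


@pytest.fixture(scope="session")
def spec() -> fx.FixtureSpec:
    return fx.FixtureSpec()


@pytest.fixture(scope="session")
def mini_plant(spec) -> MetabolicModel:
    return fx.build_mini_plant(spec)


@pytest.fixture(scope="session")
def mini_rhizobium(spec) -> MetabolicModel:
    return fx.build_mini_rhizobium(spec)


@pytest.fixture(scope="session")
def two_tissue(spec) -> MetabolicModel:
    return fx.build_two_tissue_plant(spec)


@pytest.fixture(scope="session")
def symbiotic(spec) -> MetabolicModel:
    _, model = fx.build_symbiotic_system(spec)
    return model


@pytest.fixture(scope="session")
def symbiotic_day_no_n(spec, symbiotic) -> MetabolicModel:
    model = apply_condition(symbiotic, fx.two_tissue_day_condition(spec))
    fx.two_tissue_nitrogen_condition(0.0, 0.0).apply(model)
    return model


@pytest.fixture(scope="session")
def plant_day_no_n(spec, two_tissue) -> MetabolicModel:
    model = apply_condition(two_tissue, fx.two_tissue_day_condition(spec))
    fx.two_tissue_nitrogen_condition(0.0, 0.0).apply(model)
    return model


# ---------------------------------------------------------------------------
# toy network builders
# ---------------------------------------------------------------------------


def linear_chain(n: int = 2, uptake: float = 10.0) -> MetabolicModel:
    """EX_A -> A -> ... -> Z -> EX_Z with n interior conversions."""
    m = MetabolicModel(id=f"chain{n}")
    m.add_compartment("c")
    mets = [f"m{i}_c" for i in range(n + 1)]
    for mid in mets:
        m.add_metabolite(Metabolite(mid, "c", formula={"C": 1}, charge=0))
    m.add_reaction(Reaction("EX_in", {mets[0]: -1.0}, -uptake, 0.0, kind="exchange"))
    for i in range(n):
        m.add_reaction(Reaction(f"R{i+1}", {mets[i]: -1.0, mets[i + 1]: 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("EX_out", {mets[-1]: -1.0}, 0.0, 1000.0, kind="exchange"))
    m.objective = {"EX_out": 1.0}
    return m


def parallel_routes(lengths: tuple[int, ...] = (1, 1), demand: float = 10.0) -> MetabolicModel:
    """A -> B via several routes of the given reaction counts; demand on B."""
    m = MetabolicModel(id="parallel")
    m.add_compartment("c")
    m.add_metabolite(Metabolite("a_c", "c", formula={"C": 1}, charge=0))
    m.add_metabolite(Metabolite("b_c", "c", formula={"C": 1}, charge=0))
    m.add_reaction(Reaction("EX_a", {"a_c": -1.0}, -1000.0, 0.0, kind="exchange"))
    for r, length in enumerate(lengths):
        prev = "a_c"
        for step in range(length - 1):
            mid = f"x{r}_{step}_c"
            m.add_metabolite(Metabolite(mid, "c", formula={"C": 1}, charge=0))
            m.add_reaction(Reaction(f"P{r}_{step}", {prev: -1.0, mid: 1.0}, 0.0, 1000.0))
            prev = mid
        m.add_reaction(Reaction(f"P{r}_{length-1}", {prev: -1.0, "b_c": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("EX_b", {"b_c": -1.0}, 0.0, demand, kind="exchange"))
    m.objective = {"EX_b": 1.0}
    return m


def cycle_test_model(flipped: bool = False) -> MetabolicModel:
    """A two-compartment loop that generates ATP only when the antiporter's
    directionality is (wrongly) flipped."""
    m = MetabolicModel(id="cycle_test")
    m.add_compartment("c")
    m.add_compartment("m")
    for mid, comp in [("x_c", "c"), ("x_m", "m"), ("atp_c", "c"), ("adp_c", "c"),
                      ("pi_c", "c"), ("h2o_c", "c"), ("h_c", "c")]:
        m.add_metabolite(Metabolite(mid, comp, formula={}, charge=0))
    m.add_reaction(Reaction("EX_x", {"x_c": -1.0}, -1000.0, 1000.0, kind="exchange"))
    m.add_reaction(Reaction("T_x", {"x_m": -1.0, "x_c": 1.0}, 0.0, 1000.0, kind="transport"))
    if flipped:
        # wrong direction: x_c + ADP + Pi -> x_m + ATP (downhill into the loop)
        m.add_reaction(Reaction("PUMP", {"x_c": -1.0, "adp_c": -1.0, "pi_c": -1.0,
                                         "h_c": -1.0, "x_m": 1.0, "atp_c": 1.0,
                                         "h2o_c": 1.0}, 0.0, 1000.0, kind="transport"))
    else:
        # correct direction: moving x into m costs ATP
        m.add_reaction(Reaction("PUMP", {"x_c": -1.0, "atp_c": -1.0, "h2o_c": -1.0,
                                         "x_m": 1.0, "adp_c": 1.0, "pi_c": 1.0,
                                         "h_c": 1.0}, 0.0, 1000.0, kind="transport"))
    m.add_reaction(Reaction("MAINT", {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0,
                                      "pi_c": 1.0, "h_c": 1.0}, 0.0, 1000.0,
                            kind="maintenance"))
    return m


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_fva(model_or_system, reactions=None) -> dict[str, tuple[float, float]]:
    """Plain two-LP-per-reaction flux ranges (no objective constraint)."""
    system = (model_or_system if hasattr(model_or_system, "S")
              else assemble_stoichiometric_matrix(model_or_system))
    zeros = np.zeros(system.n_metabolites)
    out = {}
    for rid in (reactions or system.col_index):
        j = system.reaction_position(rid)
        e = np.zeros(system.n_reactions)
        e[j] = 1.0
        lo = lp(e, system.S, zeros, system.lb, system.ub)
        hi = lp(-e, system.S, zeros, system.lb, system.ub)
        assert lo.status == "optimal" and hi.status == "optimal"
        out[rid] = (float(lo.x[j]), float(hi.x[j]))
    return out


def brute_force_blocked(model, eps: float = 1e-4) -> set[str]:
    """Blocked set from per-reaction flux ranges."""
    return {rid for rid, (lo, hi) in brute_force_fva(model).items()
            if max(abs(lo), abs(hi)) < eps}


def is_flux_consistent_subnetwork(model, rids, eps: float = 1e-4) -> bool:
    """Every reaction of the subnetwork can carry |v| >= eps."""
    sub = model.submodel(rids)
    return not brute_force_blocked(sub, eps)


def assert_qp_optimal(system, fixed: dict[str, float], solution, tol: float = 1e-6):
    """LP certificate that a feasible point minimises Σv².

    For the convex QP it suffices that no feasible direction d (S d = 0,
    respecting active bounds and fixed fluxes, |d| ≤ 1) improves the
    objective: min ∇f·d = 2v·d ≥ −tol.
    """
    v = np.array([solution.fluxes[r] for r in system.col_index])
    assert np.max(np.abs(system.S @ v)) < 1e-6
    lo = np.empty(system.n_reactions)
    hi = np.empty(system.n_reactions)
    for j, rid in enumerate(system.col_index):
        if rid in fixed:
            lo[j] = hi[j] = 0.0
            continue
        lo[j] = 0.0 if v[j] <= system.lb[j] + 1e-7 else -1.0
        hi[j] = 0.0 if v[j] >= system.ub[j] - 1e-7 else 1.0
    res = lp(2.0 * v, system.S, np.zeros(system.n_metabolites), lo, hi)
    assert res.status == "optimal"
    assert res.fun >= -tol, f"improving direction exists: {res.fun}"
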