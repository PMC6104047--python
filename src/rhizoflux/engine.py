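"""Constraint-based analyses: FBA, quadratic flux minimisation, FVA,
blocked-reaction (flux consistency) detection, knockout screens and
energy-generating-cycle certification.

All analyses rest on the steady-state assumption S·v = 0 of flux balance
analysis.  Flux distributions from plain FBA are generally non-unique;
the quadratic flux minimisation (min Σ vᵢ², interpreted as maximally
efficient enzyme usage) restores uniqueness and is used whenever a
*specific* flux distribution is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .model import MetabolicModel, StoichiometricSystem, assemble_stoichiometric_matrix
from .solve import FluxSolution, lp, min_norm_qp

__all__ = [
    "solve_fba",
    "minimize_quadratic_flux",
    "flux_variability",
    "find_blocked_reactions",
    "single_reaction_knockouts",
    "detect_energy_generating_cycles",
    "EssentialityResult",
    "ESSENTIALITY_THRESHOLD",
    "CONSISTENCY_EPS",
]

#: A knockout is essential when the remaining optimum falls below this
#: absolute threshold (model units) or the problem becomes infeasible.
ESSENTIALITY_THRESHOLD = 1e-6

#: Flux activation threshold for consistency checks (FASTCC/FASTCORE).
CONSISTENCY_EPS = 1e-4


def _residual(system: StoichiometricSystem, v: np.ndarray) -> float:
    if system.n_metabolites == 0:
        return 0.0
    return float(np.max(np.abs(system.S @ v))) if v is not None else float("nan")


def _as_flux_solution(system: StoichiometricSystem, x, fun, status) -> FluxSolution:
    if status != "optimal" or x is None:
        return FluxSolution({}, float("nan"), status, float("nan"))
    fluxes = dict(zip(system.col_index, map(float, x)))
    return FluxSolution(fluxes, float(fun), "optimal", _residual(system, x))


def solve_fba(
    system: StoichiometricSystem,
    sense: str = "max",
    objective: np.ndarray | str | None = None,
) -> FluxSolution:
    """Flux balance analysis: optimise a linear objective over S·v = 0.

    ``objective`` may be a reaction id, a coefficient vector, or ``None``
    to use the system's objective vector.  The optimal objective value is
    unique up to solver tolerance; the flux vector need not be.
    Infeasibility and unboundedness are reported in ``status``, never as
    a silent zero.
    """
    c = _objective_vector(system, objective)
    sign = -1.0 if sense == "max" else 1.0
    res = lp(sign * c, system.S, np.zeros(system.n_metabolites), system.lb, system.ub)
    if res.status != "optimal":
        return FluxSolution({}, float("nan"), res.status, float("nan"))
    return _as_flux_solution(system, res.x, sign * res.fun, "optimal")


def _objective_vector(system, objective) -> np.ndarray:
    if objective is None:
        return system.objective_vector
    if isinstance(objective, str):
        c = np.zeros(system.n_reactions)
        c[system.reaction_position(objective)] = 1.0
        return c
    return np.asarray(objective, dtype=float)


def minimize_quadratic_flux(
    system: StoichiometricSystem,
    fixed_constraints: list[tuple[str, float | tuple[float, float]]] | None = None,
) -> FluxSolution:
    """min Σᵢ vᵢ² over *all* reactions, subject to fixed constraints.

    A fixed constraint is either ``(reaction_id, value)``, pinning the
    flux as an equality (e.g. a fixed growth rate), or
    ``(reaction_id, (lo, hi))`` tightening the bounds.  The optimum is the
    unique projection of the origin onto the feasible polytope; repeated
    solves agree to machine precision.
    """
    lb = system.lb.copy()
    ub = system.ub.copy()
    fixed: dict[int, float] = {}
    for rid, spec in fixed_constraints or []:
        j = system.reaction_position(rid)
        if isinstance(spec, tuple):
            lo, hi = spec
            lb[j], ub[j] = float(lo), float(hi)
        else:
            fixed[j] = float(spec)
    v, status = min_norm_qp(system.S, lb, ub, fixed)
    if status != "optimal":
        return FluxSolution({}, float("nan"), status, float("nan"))
    fluxes = dict(zip(system.col_index, map(float, v)))
    return FluxSolution(fluxes, float(np.dot(v, v)), "optimal", _residual(system, v))


def flux_variability(
    system: StoichiometricSystem,
    objective_fraction: float = 1.0,
    reactions: list[str] | None = None,
    sense: str = "max",
) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux retaining a fraction of the optimum.

    Each reported endpoint is attained by a feasible flux distribution
    whose objective is ≥ fraction × optimum (for maximisation).
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in [0, 1]")
    c = system.objective_vector
    A_ub = None
    b_ub = None
    if np.any(c != 0):
        base = solve_fba(system, sense=sense)
        if not base.ok:
            raise RuntimeError(f"base FBA not optimal: {base.status}")
        if sense == "max":
            A_ub = sparse.csr_matrix(-c)
            b_ub = np.array([-objective_fraction * base.objective_value])
        else:
            A_ub = sparse.csr_matrix(c)
            b_ub = np.array([objective_fraction * base.objective_value])
    rids = reactions if reactions is not None else list(system.col_index)
    zeros = np.zeros(system.n_metabolites)
    out: dict[str, tuple[float, float]] = {}
    for rid in rids:
        j = system.reaction_position(rid)
        e = np.zeros(system.n_reactions)
        e[j] = 1.0
        lo = lp(e, system.S, zeros, system.lb, system.ub, A_ub, b_ub)
        hi = lp(-e, system.S, zeros, system.lb, system.ub, A_ub, b_ub)
        if lo.status != "optimal" or hi.status != "optimal":
            raise RuntimeError(f"FVA subproblem for {rid} ended {lo.status}/{hi.status}")
        out[rid] = (float(lo.x[j]), float(hi.x[j]))
    return out


# ---------------------------------------------------------------------------
# flux consistency (FASTCC)
# ---------------------------------------------------------------------------


def _lp7(S, lb, ub, J: list[int], eps: float) -> np.ndarray | None:
    """Support maximisation: max Σ_{j∈J} z_j, z_j ≤ min(v_j, eps), z ≥ 0."""
    m, n = S.shape
    k = len(J)
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    A_eq = sparse.hstack([S, sparse.csr_matrix((m, k))], format="csr")
    b_eq = np.zeros(m)
    # z_j - v_j <= 0
    rows = sparse.csr_matrix(
        (np.ones(k), (np.arange(k), J)), shape=(k, n)
    )
    A_ub = sparse.hstack([-rows, sparse.eye(k, format="csr")], format="csr")
    b_ub = np.zeros(k)
    lo = np.concatenate([lb, np.zeros(k)])
    hi = np.concatenate([ub, np.full(k, eps)])
    res = lp(c, A_eq, b_eq, lo, hi, A_ub, b_ub)
    if res.status != "optimal":
        return None
    return res.x[:n]


def _lp_max_single(S, lb, ub, j: int) -> np.ndarray | None:
    n = S.shape[1]
    e = np.zeros(n)
    e[j] = -1.0
    res = lp(e, S, np.zeros(S.shape[0]), lb, ub)
    return res.x if res.status == "optimal" else None


def find_blocked_reactions(
    model: MetabolicModel | StoichiometricSystem, eps: float = CONSISTENCY_EPS
) -> set[str]:
    """Reactions unable to carry |v| ≥ eps in any feasible steady state.

    Uses the FASTCC scheme: one support-maximisation LP over all
    irreversible reactions, then directional probing with sign flips for
    the remaining (mostly reversible) candidates.  The complement of the
    result is the flux-consistent part of the network under the current
    exchange configuration.
    """
    system = (
        model
        if isinstance(model, StoichiometricSystem)
        else assemble_stoichiometric_matrix(model)
    )
    n = system.n_reactions
    if n == 0:
        return set()
    S = sparse.csc_matrix(system.S, copy=True).asfptype().tolil().tocsc().astype(float)
    S = S.toarray()  # column flips are simplest densely; fixture scale is small
    lb = system.lb.copy()
    ub = system.ub.copy()

    irreversible = {j for j in range(n) if lb[j] >= 0}
    consistent: set[int] = set()

    J = sorted(irreversible)
    if J:
        v = _lp7(sparse.csc_matrix(S), lb, ub, J, eps)
        if v is not None:
            consistent |= {j for j in range(n) if abs(v[j]) >= 0.99 * eps}
    blocked_irrev = set(J) - consistent
    J_set = set(range(n)) - consistent - blocked_irrev

    flipped = False
    singleton = False
    while J_set:
        if singleton:
            Ji = [min(J_set)]
            v = _lp_max_single(sparse.csc_matrix(S), lb, ub, Ji[0])
        else:
            Ji = sorted(J_set)
            v = _lp7(sparse.csc_matrix(S), lb, ub, Ji, eps)
        if v is not None:
            consistent |= {j for j in range(n) if abs(v[j]) >= 0.99 * eps}
        if J_set & consistent:
            J_set -= consistent
            flipped = False
        else:
            ji_rev = [j for j in Ji if j not in irreversible]
            if flipped or not ji_rev:
                flipped = False
                if singleton:
                    J_set.discard(Ji[0])  # certified blocked
                else:
                    singleton = True
            else:
                for j in ji_rev:
                    S[:, j] = -S[:, j]
                    lb[j], ub[j] = -ub[j], -lb[j]
                flipped = True

    blocked = set(range(n)) - consistent
    return {system.col_index[j] for j in blocked}


# ---------------------------------------------------------------------------
# knockouts
# ---------------------------------------------------------------------------


@dataclass
class EssentialityResult:
    """Outcome of a single-reaction knockout screen.

    ``knockout_objective`` maps each tested reaction to the optimum after
    forcing its flux to zero (``None`` when the knockout renders the
    problem infeasible).  A reaction is essential when that optimum falls
    below the threshold or is infeasible; near-threshold cases (within
    10× the threshold) are additionally listed as ``borderline``.
    """

    wild_type_objective: float
    knockout_objective: dict[str, float | None]
    essential: set[str]
    borderline: set[str]
    kind_of: dict[str, str]
    threshold: float = ESSENTIALITY_THRESHOLD
    condition: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_essential(self) -> int:
        return len(self.essential)

    def essential_of_kind(self, kind: str) -> set[str]:
        return {r for r in self.essential if self.kind_of.get(r) == kind}

    @property
    def n_essential_transporters(self) -> int:
        return len(self.essential_of_kind("transport"))


def single_reaction_knockouts(
    model: MetabolicModel,
    condition=None,
    objective: str | None = None,
    threshold: float = ESSENTIALITY_THRESHOLD,
    reactions: list[str] | None = None,
) -> EssentialityResult:
    """Knock out each reaction in turn (bounds → (0,0)) and re-optimise.

    ``condition`` is an optional :class:`~rhizoflux.io.ConditionSpec`
    applied to a copy of the model first.  The wild-type optimum must
    exceed the essentiality threshold.
    """
    work = model.copy()
    if condition is not None:
        condition.apply(work)
    system = assemble_stoichiometric_matrix(work)
    wt = solve_fba(system, sense="max", objective=objective)
    if not wt.ok or wt.objective_value <= threshold:
        raise RuntimeError(
            f"wild-type optimum {wt.objective_value!r} ({wt.status}) below threshold"
        )
    c = _objective_vector(system, objective)
    rids = reactions if reactions is not None else list(system.col_index)
    ko_obj: dict[str, float | None] = {}
    essential: set[str] = set()
    borderline: set[str] = set()
    lb = system.lb
    ub = system.ub
    zeros = np.zeros(system.n_metabolites)
    for rid in rids:
        j = system.reaction_position(rid)
        keep = lb[j], ub[j]
        lb[j] = ub[j] = 0.0
        res = lp(-c, system.S, zeros, lb, ub)
        lb[j], ub[j] = keep
        if res.status != "optimal":
            ko_obj[rid] = None
            essential.add(rid)
            continue
        val = -res.fun
        ko_obj[rid] = val
        if val < threshold:
            essential.add(rid)
        elif val < 10 * threshold:
            borderline.add(rid)
    kind_of = {rid: work.reactions[rid].kind for rid in rids}
    return EssentialityResult(
        wild_type_objective=wt.objective_value,
        knockout_objective=ko_obj,
        essential=essential,
        borderline=borderline,
        kind_of=kind_of,
        threshold=threshold,
        condition=getattr(condition, "name", "") if condition is not None else "",
    )


def detect_energy_generating_cycles(
    model: MetabolicModel, energy_demand_reaction: str
) -> FluxSolution:
    """Certify absence of thermodynamically infeasible energy cycles.

    All exchange reactions are closed and the energy demand (e.g. the ATP
    maintenance hydrolysis) is maximised.  A strictly positive optimum
    certifies an energy-generating cycle; the returned flux vector
    localises it.  A curated model must yield an optimum of zero.
    """
    if energy_demand_reaction not in model.reactions:
        raise KeyError(f"unknown energy demand reaction {energy_demand_reaction}")
    work = model.copy()
    for rid in work.exchanges():
        work.set_bounds(rid, 0.0, 0.0)
    # maintenance demands may carry forced lower bounds; relax them so the
    # closed system is feasible and the demand flux is purely cycle-driven
    for rid, rxn in work.reactions.items():
        if rxn.kind == "maintenance" and rxn.lower_bound > 0:
            work.set_bounds(rid, 0.0, rxn.upper_bound)
    system = assemble_stoichiometric_matrix(work)
    return solve_fba(system, sense="max", objective=energy_demand_reaction)
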