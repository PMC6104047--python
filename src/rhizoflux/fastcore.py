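"""Context-specific subnetwork extraction with FASTCORE.

FASTCORE takes a flux-consistent network and a *core* set of reactions
that the context (e.g. a tissue's expression profile) requires to be
active, and returns a near-minimal flux-consistent subnetwork containing
the whole core.  It alternates two LPs: a support-maximisation step over
the not-yet-activated core (LP7) and an L1 flux-magnitude minimisation
over the non-core penalty set (LP10), flipping the sign of reversible
candidates when a direction fails.  The output is near-minimal, not
guaranteed minimal -- that is the algorithm's contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .engine import CONSISTENCY_EPS, find_blocked_reactions
from .gpr import evaluate_gpr, gpr_genes
from .model import MetabolicModel, assemble_stoichiometric_matrix
from .solve import lp

__all__ = [
    "CoreSet",
    "ExpressionTable",
    "FastcoreError",
    "build_core_set_from_expression",
    "fastcore_extract",
    "extract_tissue_models",
]

log = logging.getLogger(__name__)


class FastcoreError(RuntimeError):
    pass


@dataclass
class CoreSet:
    """Reactions required active in the extracted subnetwork, with the
    reason each entered the core (expression | protected | user)."""

    reactions: set[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid in self.reactions:
            self.provenance.setdefault(rid, "user")

    def union(self, other: "CoreSet") -> "CoreSet":
        prov = dict(self.provenance)
        for rid, why in other.provenance.items():
            prov.setdefault(rid, why)
        return CoreSet(self.reactions | other.reactions, prov)


@dataclass
class ExpressionTable:
    """Gene expression values (arbitrary non-negative units) per tissue."""

    data: pd.DataFrame  # index: gene ids, columns: tissues

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    @property
    def tissues(self) -> list[str]:
        return list(self.data.columns)

    def tissue_values(self, tissue: str) -> dict[str, float]:
        return self.data[tissue].to_dict()


def build_core_set_from_expression(
    model: MetabolicModel,
    expr: ExpressionTable,
    tissue: str,
    threshold: float,
) -> CoreSet:
    """Score each reaction's GPR against a tissue expression profile.

    The activity score evaluates the GPR with OR→max (isozymes) and
    AND→min (complexes); a reaction enters the core iff score ≥
    threshold.  Reactions without a GPR are excluded (FASTCORE may pull
    them in as support).  Genes missing from the table score 0 and are
    logged.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    values = expr.tissue_values(tissue)
    missing: set[str] = set()
    core: set[str] = set()
    for rid, rxn in model.reactions.items():
        if not rxn.gpr:
            continue
        absent = gpr_genes(rxn.gpr) - set(values)
        missing |= absent
        score = evaluate_gpr(rxn.gpr, values, missing=0.0)
        if score >= threshold:
            core.add(rid)
    if missing:
        log.warning("tissue %s: %d GPR genes missing from expression table "
                    "(scored 0): %s", tissue, len(missing), sorted(missing))
    return CoreSet(core, {rid: "expression" for rid in core})


# ---------------------------------------------------------------------------
# the algorithm
# ---------------------------------------------------------------------------


def _lp7(S, lb, ub, J: list[int], eps: float) -> np.ndarray | None:
    """max |{j in J : v_j >= eps}| via the standard LP relaxation."""
    m, n = S.shape
    k = len(J)
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    A_eq = sparse.hstack([S, sparse.csr_matrix((m, k))], format="csr")
    rows = sparse.csr_matrix((np.ones(k), (np.arange(k), J)), shape=(k, n))
    A_ub = sparse.hstack([-rows, sparse.eye(k, format="csr")], format="csr")
    res = lp(c, A_eq, np.zeros(m), np.concatenate([lb, np.zeros(k)]),
             np.concatenate([ub, np.full(k, eps)]), A_ub, np.zeros(k))
    return res.x[:n] if res.status == "optimal" else None


def _lp10(S, lb, ub, K: list[int], P: list[int], eps: float,
          scaling: float = 1e5) -> np.ndarray | None:
    """min Σ_{p∈P} |v_p| s.t. S v = 0, v_k ≥ eps (k∈K), bounds.

    All bounds are scaled up (by 1e5, as in the reference formulation) so
    that reactions stoichiometrically coupled to the forced core carry
    fluxes comfortably above the support threshold; without the scaling a
    partner reaction running at a small fixed ratio of a core flux would
    drop below eps and the extracted network could contain blocked
    leftovers.
    """
    m, n = S.shape
    npen = len(P)
    lo = lb * scaling
    hi = ub * scaling
    lo[K] = np.maximum(lo[K], eps * scaling)
    if npen == 0:
        res = lp(np.zeros(n), S, np.zeros(m), lo, hi)
        return res.x if res.status == "optimal" else None
    c = np.concatenate([np.zeros(n), np.ones(npen)])
    A_eq = sparse.hstack([S, sparse.csr_matrix((m, npen))], format="csr")
    rows = sparse.csr_matrix((np.ones(npen), (np.arange(npen), P)), shape=(npen, n))
    eye = sparse.eye(npen, format="csr")
    A_ub = sparse.vstack(
        [sparse.hstack([rows, -eye]), sparse.hstack([-rows, -eye])], format="csr"
    )
    zcap = np.maximum(np.abs(lo[P]), np.abs(hi[P]))
    res = lp(c, A_eq, np.zeros(m),
             np.concatenate([lo, np.zeros(npen)]),
             np.concatenate([hi, zcap]),
             A_ub, np.zeros(2 * npen))
    return res.x[:n] if res.status == "optimal" else None


def _find_sparse_mode(S, lb, ub, J: list[int], P: list[int], singleton: bool,
                      eps: float) -> set[int]:
    if not J:
        return set()
    v = _lp7(S, lb, ub, J[:1] if singleton else J, eps)
    if v is None:
        return set()
    K = [j for j in (J[:1] if singleton else J) if v[j] >= 0.99 * eps]
    if not K:
        return set()
    v = _lp10(sparse.csc_matrix(S), lb, ub, K, P, eps)
    if v is None:
        return set()
    return {j for j in range(S.shape[1]) if abs(v[j]) >= 0.99 * eps}


def _fastcore_indices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                      core: set[int], eps: float,
                      names: list[str]) -> set[int]:
    n = S.shape[1]
    lb = lb.copy()
    ub = ub.copy()
    S = S.copy()
    irreversible = {j for j in range(n) if lb[j] >= 0}
    flipped = False
    singleton = False

    J = sorted(core & irreversible)
    P = sorted(set(range(n)) - core)
    A = _find_sparse_mode(sparse.csc_matrix(S), lb, ub, J, P, False, eps)
    bad = set(J) - A
    if bad:
        raise FastcoreError(
            "inconsistent irreversible core reactions: "
            + ", ".join(names[j] for j in sorted(bad))
        )
    J = core - A
    while J:
        P = sorted(set(P) - A)
        Ji = [min(J)] if singleton else sorted(J)
        supp = _find_sparse_mode(sparse.csc_matrix(S), lb, ub, Ji, P, singleton, eps)
        A |= supp
        if J & A:
            J -= A
            flipped = False
        else:
            ji_rev = [j for j in Ji if j not in irreversible]
            if flipped or not ji_rev:
                if singleton:
                    raise FastcoreError(
                        f"core reaction {names[min(J)]} cannot be activated "
                        "(global network inconsistency)"
                    )
                flipped = False
                singleton = True
            else:
                for j in ji_rev:
                    S[:, j] = -S[:, j]
                    lb[j], ub[j] = -ub[j], -lb[j]
                flipped = True
    return A


def fastcore_extract(
    model: MetabolicModel, core: CoreSet, eps: float = CONSISTENCY_EPS
) -> MetabolicModel:
    """Extract the near-minimal flux-consistent subnetwork containing
    ``core``.

    The input is first reduced to its flux-consistent part; a core
    reaction inside the blocked set is an error (it can never be
    activated).  The output contains the entire core and every reaction
    in it can carry |v| ≥ eps.
    """
    unknown = core.reactions - set(model.reactions)
    if unknown:
        raise FastcoreError(f"core reactions not in model: {sorted(unknown)}")
    blocked = find_blocked_reactions(model, eps)
    offenders = core.reactions & blocked
    if offenders:
        raise FastcoreError(
            "core reactions blocked in the input model: " + ", ".join(sorted(offenders))
        )
    consistent = model.submodel(
        [r for r in model.reactions if r not in blocked], id_suffix="_consistent"
    )
    system = assemble_stoichiometric_matrix(consistent)
    names = list(system.col_index)
    idx = {r: j for j, r in enumerate(names)}
    core_idx = {idx[r] for r in core.reactions}
    S = np.asarray(system.S.todense(), dtype=float)
    A = _fastcore_indices(S, system.lb, system.ub, core_idx, eps, names)
    assert core_idx <= A, "FASTCORE postcondition violated: core not covered"
    return model.submodel(sorted(names[j] for j in A), id_suffix="_" + "core")


def extract_tissue_models(
    model: MetabolicModel,
    expr: ExpressionTable,
    tissues: list[str],
    threshold: float,
    protected: list[str] | dict[str, list[str]] | None = None,
    eps: float = CONSISTENCY_EPS,
) -> dict[str, MetabolicModel]:
    """Per-tissue extraction: expression core + protected reactions →
    FASTCORE.

    Biomass reactions and, by default, boundary reactions (exchanges and
    maintenance demands, which are never expression-gated) are always
    added to the core, restricted to the flux-consistent part of the
    input.  ``protected`` may be one list for all tissues or a per-tissue
    mapping (tissue boundaries genuinely differ: a root has no photon
    exchange).
    """
    if protected is None:
        protected = model.reactions_of_kind("exchange", "maintenance")
    blocked = find_blocked_reactions(model, eps)
    out: dict[str, MetabolicModel] = {}
    for tissue in tissues:
        tissue_protected = (
            protected.get(tissue, []) if isinstance(protected, dict) else protected
        )
        always = set(tissue_protected) | set(model.reactions_of_kind("biomass"))
        expr_core = build_core_set_from_expression(model, expr, tissue, threshold)
        keep = CoreSet(
            (expr_core.reactions | always) - blocked,
            {**{r: "protected" for r in always}, **expr_core.provenance},
        )
        sub = fastcore_extract(model, keep, eps)
        sub.id = f"{model.id}_{tissue}"
        out[tissue] = sub
    return out
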