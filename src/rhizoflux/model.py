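"""Core data structures for compartmentalised metabolic models.

A :class:`MetabolicModel` is the central artifact: compartments,
metabolites carrying elemental formulas and charges, reactions carrying
stoichiometry, flux bounds and gene--protein--reaction (GPR) rules, and a
linear objective.  Fluxes are in mmol·gDW⁻¹·day⁻¹ except for biomass
reactions, whose flux is a growth rate in g·gDW⁻¹·day⁻¹.

Sign convention: substrates carry negative stoichiometric coefficients,
products positive ones.  Exchange reactions are written as
``species -> (nothing)`` so that uptake is a *negative* flux and export a
positive one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "StoichiometricSystem",
    "BalanceReport",
    "ValidationReport",
    "ModelIntegrityError",
    "parse_formula",
    "format_formula",
    "assemble_stoichiometric_matrix",
    "check_reaction_balance",
    "validate_model",
    "BALANCE_TOL",
    "DEFAULT_BOUND",
    "REACTION_KINDS",
]

#: Tolerance on element and charge deltas: stoichiometries may be
#: real-valued (e.g. biomass coefficients), so balance is checked within a
#: numerical tolerance rather than exactly.
BALANCE_TOL = 1e-6

#: Conventional "unbounded" sentinel magnitude for flux bounds.
DEFAULT_BOUND = 1000.0

REACTION_KINDS = ("internal", "transport", "exchange", "biomass", "maintenance")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelIntegrityError(ValueError):
    """A structural defect: dangling references, bad bounds, bad kinds."""


def parse_formula(text: str) -> dict[str, float]:
    """Parse an elemental formula string such as ``C5H8NO4`` into a map.

    An empty string denotes a massless species (e.g. a photon) and yields
    an empty map, which is *verifiable* (zero atoms of every element), in
    contrast to a missing (``None``) formula.
    """
    text = text.strip()
    if not text:
        return {}
    counts: dict[str, float] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"unparseable formula {text!r} at position {pos}")
        element, number = match.groups()
        value = float(number) if number else 1.0
        counts[element] = counts.get(element, 0.0) + value
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"unparseable formula {text!r} at position {pos}")
    return counts


def format_formula(counts: Mapping[str, float] | None) -> str:
    """Render a formula map in Hill-like order (C, H, then alphabetical)."""
    if counts is None:
        return ""
    def key(el: str) -> tuple[int, str]:
        return ({"C": 0, "H": 1}.get(el, 2), el)
    parts = []
    for el in sorted(counts, key=key):
        n = counts[el]
        if n == 0:
            continue
        if float(n).is_integer():
            parts.append(el + (str(int(n)) if n != 1 else ""))
        else:
            parts.append(f"{el}{n:g}")
    return "".join(parts)


@dataclass
class Metabolite:
    """A chemical species in a specific compartment.

    ``formula`` maps element symbols to (usually integral) counts; ``None``
    means unknown, in which case balance checks involving this species are
    *unverifiable*.  ``charge`` is the net ionic charge, again ``None`` if
    unknown.  By convention metabolite ids carry a compartment suffix
    ("_c", "_p", ...) but the ``compartment`` field is authoritative.
    """

    id: str
    compartment: str
    name: str = ""
    formula: dict[str, float] | None = None
    charge: float | None = None

    def __post_init__(self) -> None:
        if self.formula is not None:
            for el, n in self.formula.items():
                if n < 0:
                    raise ValueError(f"negative count for {el} in {self.id}")

    def copy(self) -> "Metabolite":
        return replace(self, formula=dict(self.formula) if self.formula is not None else None)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``kind`` distinguishes internal conversions, membrane transports,
    boundary exchanges, the biomass pseudo-reaction and maintenance
    demands; exchange and biomass reactions are exempt from mass/charge
    balance requirements.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    kind: str = "internal"
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelIntegrityError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelIntegrityError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelIntegrityError(f"reaction {self.id}: empty stoichiometry")
        for met, coeff in self.stoichiometry.items():
            if coeff == 0:
                raise ModelIntegrityError(
                    f"reaction {self.id}: zero coefficient for {met}"
                )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def substrates(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A compartmentalised metabolic network.

    Metabolites and reactions are kept in insertion-ordered dicts keyed by
    id; the objective maps reaction ids to linear weights.
    """

    id: str = "model"
    compartments: dict[str, str] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)

    # -- construction -------------------------------------------------

    def add_compartment(self, cid: str, name: str = "") -> None:
        self.compartments.setdefault(cid, name or cid)

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelIntegrityError(f"duplicate metabolite id {met.id}")
        if met.compartment not in self.compartments:
            raise ModelIntegrityError(
                f"metabolite {met.id}: undeclared compartment {met.compartment!r}"
            )
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelIntegrityError(f"duplicate reaction id {rxn.id}")
        for met in rxn.stoichiometry:
            if met not in self.metabolites:
                raise ModelIntegrityError(
                    f"reaction {rxn.id} references unknown metabolite {met}"
                )
        self.reactions[rxn.id] = rxn

    # -- queries ------------------------------------------------------

    def reaction_compartments(self, rid: str) -> set[str]:
        rxn = self.reactions[rid]
        return {self.metabolites[m].compartment for m in rxn.stoichiometry}

    def reactions_of_kind(self, *kinds: str) -> list[str]:
        return [r.id for r in self.reactions.values() if r.kind in kinds]

    def exchanges(self) -> list[str]:
        return self.reactions_of_kind("exchange")

    def genes(self) -> set[str]:
        from .gpr import gpr_genes

        out: set[str] = set()
        for rxn in self.reactions.values():
            if rxn.gpr:
                out |= gpr_genes(rxn.gpr)
        return out

    def check_integrity(self) -> None:
        """Raise :class:`ModelIntegrityError` on dangling references."""
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ModelIntegrityError(
                        f"reaction {rxn.id} references unknown metabolite {met}"
                    )
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelIntegrityError(
                    f"metabolite {met.id}: undeclared compartment {met.compartment!r}"
                )
        for rid in self.objective:
            if rid not in self.reactions:
                raise ModelIntegrityError(f"objective references unknown reaction {rid}")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            compartments=dict(self.compartments),
            metabolites={m.id: m.copy() for m in self.metabolites.values()},
            reactions={r.id: r.copy() for r in self.reactions.values()},
            objective=dict(self.objective),
        )

    def set_bounds(self, rid: str, lower: float, upper: float) -> None:
        if rid not in self.reactions:
            raise ModelIntegrityError(f"unknown reaction {rid}")
        if lower > upper:
            raise ModelIntegrityError(f"{rid}: lower bound {lower} > upper bound {upper}")
        rxn = self.reactions[rid]
        rxn.lower_bound = lower
        rxn.upper_bound = upper

    def knock_out(self, *rids: str) -> None:
        for rid in rids:
            self.set_bounds(rid, 0.0, 0.0)

    def remove_reactions(self, rids: Iterable[str], prune_metabolites: bool = True) -> None:
        for rid in rids:
            self.reactions.pop(rid, None)
            self.objective.pop(rid, None)
        if prune_metabolites:
            used = {m for r in self.reactions.values() for m in r.stoichiometry}
            for mid in list(self.metabolites):
                if mid not in used:
                    del self.metabolites[mid]

    def submodel(self, rids: Iterable[str], id_suffix: str = "_sub") -> "MetabolicModel":
        """Restriction of the model to a reaction subset (metabolites pruned)."""
        keep = set(rids)
        unknown = keep - set(self.reactions)
        if unknown:
            raise ModelIntegrityError(f"unknown reactions: {sorted(unknown)}")
        sub = MetabolicModel(id=self.id + id_suffix, compartments=dict(self.compartments))
        used = {m for rid in self.reactions if rid in keep
                for m in self.reactions[rid].stoichiometry}
        for mid, met in self.metabolites.items():
            if mid in used:
                sub.metabolites[mid] = met.copy()
        for rid, rxn in self.reactions.items():
            if rid in keep:
                sub.reactions[rid] = rxn.copy()
        sub.objective = {r: w for r, w in self.objective.items() if r in keep}
        return sub


@dataclass
class StoichiometricSystem:
    """The matrix form S·v consumed by the solvers.

    Rows are metabolites, columns reactions, both in model insertion
    order; ``S[i, j]`` is the coefficient of metabolite ``i`` in reaction
    ``j``.  The steady-state constraint of flux balance analysis is
    S·v = 0: internal concentrations do not change over time.
    """

    S: sparse.csc_matrix
    row_index: list[str]
    col_index: list[str]
    lb: np.ndarray
    ub: np.ndarray
    objective_vector: np.ndarray

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    def column(self, rid: str) -> dict[str, float]:
        """Reconstruct a reaction stoichiometry from its matrix column."""
        j = self.col_index.index(rid)
        col = self.S.getcol(j).tocoo()
        return {self.row_index[i]: v for i, v in zip(col.row, col.data)}

    def reaction_position(self, rid: str) -> int:
        try:
            return self.col_index.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction {rid}") from None


def assemble_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricSystem:
    """Build the stoichiometric system S, bounds and objective vector.

    The matrix has one row per metabolite and one column per reaction;
    disassembling any column reproduces the reaction stoichiometry
    exactly.
    """
    model.check_integrity()
    row_index = list(model.metabolites)
    col_index = list(model.reactions)
    row_of = {m: i for i, m in enumerate(row_index)}
    data, rows, cols = [], [], []
    for j, rid in enumerate(col_index):
        for met, coeff in model.reactions[rid].stoichiometry.items():
            rows.append(row_of[met])
            cols.append(j)
            data.append(float(coeff))
    S = sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(row_index), len(col_index))
    )
    lb = np.array([model.reactions[r].lower_bound for r in col_index], dtype=float)
    ub = np.array([model.reactions[r].upper_bound for r in col_index], dtype=float)
    obj = np.zeros(len(col_index))
    for rid, w in model.objective.items():
        obj[col_index.index(rid)] = w
    return StoichiometricSystem(S, row_index, col_index, lb, ub, obj)


@dataclass
class BalanceReport:
    """Mass/charge balance of a single reaction.

    ``element_deltas`` holds products-minus-substrates totals per element;
    ``charge_delta`` is Σ coeff·charge.  ``status`` is ``balanced`` when
    every delta is within :data:`BALANCE_TOL`, ``imbalanced`` otherwise,
    and ``unverifiable`` when a participating species lacks a formula or
    charge.  Transport reactions are evaluated over the whole reaction:
    charge may move between compartments, but totals must still balance.
    """

    reaction_id: str
    element_deltas: dict[str, float]
    charge_delta: float | None
    status: str  # balanced | imbalanced | unverifiable
    missing: list[str] = field(default_factory=list)

    @property
    def balanced(self) -> bool:
        return self.status == "balanced"


def check_reaction_balance(
    reaction: Reaction,
    species: Mapping[str, Metabolite],
    tol: float = BALANCE_TOL,
) -> BalanceReport:
    """Element and charge bookkeeping for one reaction.

    Protons are ordinary compartment-specific metabolites (formula H,
    charge +1); no implicit proton balancing is performed.
    """
    deltas: dict[str, float] = {}
    charge_delta = 0.0
    missing: list[str] = []
    charge_known = True
    for mid, coeff in reaction.stoichiometry.items():
        met = species[mid]
        if met.formula is None:
            missing.append(mid)
        else:
            for el, n in met.formula.items():
                deltas[el] = deltas.get(el, 0.0) + coeff * n
        if met.charge is None:
            charge_known = False
            if mid not in missing:
                missing.append(mid)
        else:
            charge_delta += coeff * met.charge
    deltas = {el: d for el, d in deltas.items()}
    if missing:
        return BalanceReport(reaction.id, deltas, charge_delta if charge_known else None,
                             "unverifiable", missing)
    ok = all(abs(d) <= tol for d in deltas.values()) and abs(charge_delta) <= tol
    return BalanceReport(reaction.id, deltas, charge_delta,
                         "balanced" if ok else "imbalanced")


@dataclass
class ValidationReport:
    """Model-wide validation: balance per reaction, orphans, bound sanity.

    Exchange and biomass reactions are exempt from the balance
    requirement (they intentionally create or destroy matter); internal,
    transport and maintenance imbalances are listed in ``imbalanced``.
    """

    model_id: str
    balance: dict[str, BalanceReport]
    imbalanced: list[str]
    unverifiable: list[str]
    orphan_metabolites: list[str]
    bound_errors: list[str]

    @property
    def ok(self) -> bool:
        return not self.imbalanced and not self.bound_errors


_BALANCE_EXEMPT_KINDS = {"exchange", "biomass"}


def validate_model(model: MetabolicModel, tol: float = BALANCE_TOL) -> ValidationReport:
    """Run the full validation suite over a model.

    Deterministic and idempotent: validating twice yields identical
    reports.
    """
    model.check_integrity()
    balance: dict[str, BalanceReport] = {}
    imbalanced: list[str] = []
    unverifiable: list[str] = []
    for rid, rxn in model.reactions.items():
        report = check_reaction_balance(rxn, model.metabolites, tol)
        balance[rid] = report
        if rxn.kind in _BALANCE_EXEMPT_KINDS:
            continue
        if report.status == "imbalanced":
            imbalanced.append(rid)
        elif report.status == "unverifiable":
            unverifiable.append(rid)
    used = {m for r in model.reactions.values() for m in r.stoichiometry}
    orphans = [m for m in model.metabolites if m not in used]
    bound_errors = [
        r.id
        for r in model.reactions.values()
        if r.lower_bound > r.upper_bound
        or not np.isfinite(r.lower_bound)
        and r.lower_bound > 0
    ]
    return ValidationReport(model.id, balance, imbalanced, unverifiable, orphans, bound_errors)
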