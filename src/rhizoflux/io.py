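"""Model and configuration I/O.

TSV is the canonical fixture format (human-reviewable diffs): a reaction
table (id, equation, lb, ub, gpr, kind) plus a metabolite table
(id, compartment, formula, charge).  SBML Level 3 with the FBC package is
the interchange format, read and written through libSBML.  Condition and
scan configurations are YAML documents.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
    format_formula,
    parse_formula,
)

__all__ = [
    "ConditionSpec",
    "ScanSpec",
    "parse_equation",
    "format_equation",
    "read_model_table",
    "write_model_table",
    "read_model_sbml",
    "write_model_sbml",
    "read_condition_config",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# conditions
# ---------------------------------------------------------------------------


@dataclass
class ConditionSpec:
    """Named bound overrides (day/night, N source, O2 cap ...).

    Overrides are validated against the target model when applied, not on
    read; application is atomic -- an unknown reaction id raises before
    any mutation.
    """

    name: str
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    objective_override: dict[str, float] | None = None

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        unknown = [r for r in self.bound_overrides if r not in model.reactions]
        if self.objective_override:
            unknown += [r for r in self.objective_override if r not in model.reactions]
        if unknown:
            raise ModelIntegrityError(
                f"condition {self.name!r} references unknown reactions: {sorted(set(unknown))}"
            )
        for rid, (lo, hi) in self.bound_overrides.items():
            model.set_bounds(rid, float(lo), float(hi))
        if self.objective_override is not None:
            model.objective = {r: float(w) for r, w in self.objective_override.items()}
        return model

    def stacked(self, other: "ConditionSpec", name: str | None = None) -> "ConditionSpec":
        """Compose two conditions; the later one wins on conflicts."""
        bounds = dict(self.bound_overrides)
        bounds.update(other.bound_overrides)
        obj = other.objective_override or self.objective_override
        return ConditionSpec(name or f"{self.name}+{other.name}", bounds, obj)


@dataclass
class ScanSpec:
    """A declarative scan grid read from configuration."""

    name: str
    kind: str  # "nitrogen" | "oxygen" | generic
    parameters: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reaction equations
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "->", "=>")
_NUMBER = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``"A_c + 2 B_c -> C_m"`` into (stoichiometry, reversible).

    ``->`` denotes an irreversible reaction, ``<=>`` a reversible one.
    Either side may be empty (exchange reactions).  Coefficients may be
    real-valued.
    """
    arrow = None
    for cand in _ARROWS:
        if cand in text:
            arrow = cand
            break
    if arrow is None:
        raise ValueError(f"equation {text!r}: no arrow ('->' or '<=>') found")
    left, right = text.split(arrow, 1)
    reversible = arrow in ("<=>", "<->")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ValueError(f"equation {text!r}: empty term")
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2 and _NUMBER.match(parts[0]):
                coeff, met = float(parts[0]), parts[1]
            else:
                raise ValueError(f"equation {text!r}: cannot parse term {term!r}")
            if _NUMBER.match(met):
                raise ValueError(f"equation {text!r}: metabolite missing in term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise ValueError(f"equation {text!r}: empty stoichiometry")
    return stoich, reversible


def _coeff_str(c: float) -> str:
    return f"{int(c)}" if float(c).is_integer() else f"{c:g}"


def format_equation(rxn: Reaction) -> str:
    subs = sorted((m, c) for m, c in rxn.stoichiometry.items() if c < 0)
    prods = sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0)

    def side(terms):
        return " + ".join(
            m if abs(c) == 1 else f"{_coeff_str(abs(c))} {m}" for m, c in terms
        )

    arrow = "<=>" if rxn.reversible else "->"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

_MET_COLUMNS = ["id", "compartment", "formula", "charge", "name"]
_RXN_COLUMNS = ["id", "equation", "lb", "ub", "gpr", "kind", "objective", "name"]


def read_model_table(reactions_tsv: str | Path, metabolites_tsv: str | Path,
                     model_id: str = "model") -> MetabolicModel:
    """Load a model from the tabular fixture format."""
    import csv

    model = MetabolicModel(id=model_id)
    with open(metabolites_tsv, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                formula = row.get("formula", "")
                charge = row.get("charge", "")
                met = Metabolite(
                    id=row["id"],
                    compartment=row["compartment"],
                    name=row.get("name", "") or "",
                    # "NA" = unknown; empty = massless (e.g. photon)
                    formula=None if formula in ("NA", None) else parse_formula(formula),
                    charge=None if charge in ("", "NA", None) else float(charge),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{metabolites_tsv}:{lineno}: {exc}") from exc
            model.add_compartment(met.compartment)
            model.add_metabolite(met)
    with open(reactions_tsv, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                stoich, reversible = parse_equation(row["equation"])
                lb = row.get("lb", "")
                ub = row.get("ub", "")
                lower = float(lb) if lb not in ("", None) else (
                    -DEFAULT_BOUND if reversible else 0.0
                )
                upper = float(ub) if ub not in ("", None) else DEFAULT_BOUND
                rxn = Reaction(
                    id=row["id"],
                    stoichiometry=stoich,
                    lower_bound=lower,
                    upper_bound=upper,
                    gpr=row.get("gpr", "") or "",
                    kind=row.get("kind", "") or "internal",
                    name=row.get("name", "") or "",
                )
            except (KeyError, ValueError, ModelIntegrityError) as exc:
                raise ValueError(f"{reactions_tsv}:{lineno}: {exc}") from exc
            model.add_reaction(rxn)
            weight = row.get("objective", "")
            if weight not in ("", "0", None):
                model.objective[rxn.id] = float(weight)
    model.check_integrity()
    return model


def write_model_table(model: MetabolicModel, reactions_tsv: str | Path,
                      metabolites_tsv: str | Path) -> None:
    """Write the tabular form; output ordering follows the model."""
    import csv

    with open(metabolites_tsv, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MET_COLUMNS)
        for met in model.metabolites.values():
            w.writerow([
                met.id,
                met.compartment,
                "NA" if met.formula is None else format_formula(met.formula),
                "" if met.charge is None else _coeff_str(met.charge),
                met.name,
            ])
    with open(reactions_tsv, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_RXN_COLUMNS)
        for rxn in model.reactions.values():
            w.writerow([
                rxn.id,
                format_equation(rxn),
                _coeff_str(rxn.lower_bound),
                _coeff_str(rxn.upper_bound),
                rxn.gpr,
                rxn.kind,
                _coeff_str(model.objective.get(rxn.id, 0)) if rxn.id in model.objective else "",
                rxn.name,
            ])


# ---------------------------------------------------------------------------
# SBML (Level 3 + FBC)
# ---------------------------------------------------------------------------

_MASSLESS_ANNOTATION = '<massless xmlns="https://rhizoflux.dev/ns"/>'

_KIND_SBO = {
    "internal": "SBO:0000176",
    "transport": "SBO:0000185",
    "exchange": "SBO:0000627",
    "biomass": "SBO:0000629",
    "maintenance": "SBO:0000630",
}
_SBO_KIND = {v: k for k, v in _KIND_SBO.items()}


def write_model_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write SBML L3V1 with the FBC v2 package; lossless and
    deterministic (fixed ordering: same model, byte-identical file)."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml = doc.createModel()
    sbml.setId(model.id)
    mplug = sbml.getPlugin("fbc")
    mplug.setStrict(True)

    for cid in sorted(model.compartments):
        comp = sbml.createCompartment()
        comp.setId(cid)
        comp.setName(model.compartments[cid])
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml.createSpecies()
        sp.setId(met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        if met.formula:
            splug.setChemicalFormula(format_formula(met.formula))
        elif met.formula is not None:
            # massless species (e.g. photons): FBC cannot hold an empty
            # formula, so mark them with a tiny custom annotation
            sp.setAnnotation(_MASSLESS_ANNOTATION)

    # bound parameters, shared when identical
    bound_params: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            par.setSBOTerm("SBO:0000625")
            bound_params[value] = pid
        return bound_params[value]

    genes: dict[str, str] = {}

    def gene_id(g: str) -> str:
        if g not in genes:
            gp = mplug.createGeneProduct()
            gid = "G_" + re.sub(r"[^A-Za-z0-9_]", "_", g)
            gp.setId(gid)
            gp.setLabel(g)
            genes[g] = gid
        return genes[g]

    for rxn in model.reactions.values():
        rx = sbml.createReaction()
        rx.setId(rxn.id)
        if rxn.name:
            rx.setName(rxn.name)
        rx.setReversible(rxn.lower_bound < 0)
        rx.setFast(False)
        rx.setSBOTerm(_KIND_SBO[rxn.kind])
        for met, coeff in rxn.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_id(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_id(rxn.upper_bound))
        if rxn.gpr:
            from .gpr import parse_gpr

            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(_gpr_infix(parse_gpr(rxn.gpr), gene_id), True, False)

    if model.objective:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        for rid, weight in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(float(weight))

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"cannot write SBML to {path}")


def _gpr_infix(node, gene_id) -> str:
    if isinstance(node, str):
        return gene_id(node)
    op, children = node
    joiner = " and " if op == "and" else " or "
    return "(" + joiner.join(_gpr_infix(c, gene_id) for c in children) + ")"


class SBMLParseError(ValueError):
    pass


def read_model_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML L3+FBC model.

    Formulas and charges come from FBC species attributes when present;
    missing flux bounds default to ±1000 (logged).  Malformed XML raises
    :class:`SBMLParseError` carrying the line number; no partial model is
    returned.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml = doc.getModel()
    if sbml is None:
        raise SBMLParseError(f"{path}: no model element found")

    model = MetabolicModel(id=sbml.getId() or "model")
    for i in range(sbml.getNumCompartments()):
        comp = sbml.getCompartment(i)
        model.add_compartment(comp.getId(), comp.getName() or comp.getId())

    for i in range(sbml.getNumSpecies()):
        sp = sbml.getSpecies(i)
        splug = sp.getPlugin("fbc")
        charge = None
        formula = None
        if splug is not None:
            if splug.isSetCharge():
                charge = float(splug.getCharge())
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
        if formula is None and sp.isSetAnnotation() and \
                "massless" in sp.getAnnotationString():
            formula = {}
        model.add_metabolite(
            Metabolite(sp.getId(), sp.getCompartment(), sp.getName() or "",
                       formula, charge)
        )

    genes: dict[str, str] = {}
    mplug = sbml.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            genes[gp.getId()] = gp.getLabel() or gp.getId()

    params = {
        sbml.getParameter(i).getId(): sbml.getParameter(i).getValue()
        for i in range(sbml.getNumParameters())
    }

    for i in range(sbml.getNumReactions()):
        rx = sbml.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb = ub = None
        gpr = ""
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound())
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr = _association_to_rule(gpa.getAssociation(), genes)
        if lb is None:
            lb = -DEFAULT_BOUND if rx.getReversible() else 0.0
            log.warning("reaction %s: missing lower bound, default %g applied",
                        rx.getId(), lb)
        if ub is None:
            ub = DEFAULT_BOUND
            log.warning("reaction %s: missing upper bound, default %g applied",
                        rx.getId(), ub)
        kind = _SBO_KIND.get(rx.getSBOTermID(), "")
        if not kind:
            sides = {c > 0 for c in stoich.values()}
            if len(sides) == 1:
                kind = "exchange"
            else:
                comps = {model.metabolites[m].compartment for m in stoich}
                kind = "transport" if len(comps) > 1 else "internal"
        model.add_reaction(
            Reaction(rx.getId(), stoich, float(lb), float(ub), gpr, kind,
                     rx.getName() or "")
        )

    if mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is not None:
            for i in range(obj.getNumFluxObjectives()):
                fo = obj.getFluxObjective(i)
                model.objective[fo.getReaction()] = float(fo.getCoefficient())
    model.check_integrity()
    return model


def _association_to_rule(assoc, genes: dict[str, str]) -> str:
    import libsbml

    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        return genes.get(assoc.getGeneProduct(), assoc.getGeneProduct())
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_association_to_rule(assoc.getAssociation(i), genes)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_association_to_rule(assoc.getAssociation(i), genes)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    return ""


# ---------------------------------------------------------------------------
# condition / scan configuration (YAML)
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"conditions", "scans", "linkers", "symbiosis"}


def read_condition_config(path: str | Path) -> list[ConditionSpec | ScanSpec]:
    """Read named conditions and scan grids from a YAML document.

    Unknown top-level keys raise; an empty file yields an empty list.
    Validation against a model happens on application, not on read.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return []
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    out: list[ConditionSpec | ScanSpec] = []
    for name, body in (data.get("conditions") or {}).items():
        extra = set(body) - {"bounds", "objective"}
        if extra:
            raise ValueError(f"{path}: condition {name!r}: unknown keys {sorted(extra)}")
        bounds = {
            rid: (float(pair[0]), float(pair[1]))
            for rid, pair in (body.get("bounds") or {}).items()
        }
        objective = body.get("objective")
        if objective is not None:
            objective = {r: float(w) for r, w in objective.items()}
        out.append(ConditionSpec(name, bounds, objective))
    for name, body in (data.get("scans") or {}).items():
        body = dict(body or {})
        kind = body.pop("kind", "generic")
        out.append(ScanSpec(name, kind, body))
    return out
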