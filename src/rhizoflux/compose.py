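"""Model composition: tissue replication, inter-tissue transporters,
combined biomass, and plant-symbiont coupling.

A multi-tissue plant model is built by duplicating the base network once
per tissue (prefixing all identifiers) and adding explicit inter-tissue
transport reactions plus a combined biomass reaction drawing on the
tissue biomasses in fixed proportions.  The nitrogen-fixing symbiont is
attached to the root tissue as a non-growing flux subsystem
(differentiated bacteroids): its reactions are prefixed, its bounds
scaled to per-gram-plant units by the symbiont mass fraction f, and a
small set of literature-motivated metabolite exchanges (dicarboxylates,
glutamate, oxygen in; alanine, ammonia out) connects the two organisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ConditionSpec
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
)

__all__ = [
    "LinkerSpec",
    "ExchangeLink",
    "SymbiosisSpec",
    "replicate_into_tissues",
    "add_linker_reactions",
    "merge_biomass",
    "attach_symbiont",
    "apply_condition",
]


@dataclass(frozen=True)
class LinkerSpec:
    """One inter-tissue transporter for a metabolite.

    ``metabolite`` is the un-prefixed metabolite id of the base model;
    the linker moves it from ``from_tissue`` to ``to_tissue``
    (reversibly, if flagged).
    """

    metabolite: str
    from_tissue: str
    to_tissue: str
    reversible: bool = False


@dataclass(frozen=True)
class ExchangeLink:
    """One plant↔symbiont exchange.

    ``symbiont_metabolite`` (un-prefixed id in the symbiont model) is
    connected to ``plant_metabolite`` (id in the combined plant model,
    tissue prefix included).  Direction follows the bounds: positive flux
    moves plant → symbiont.  ``plant_cofactors`` allows protonation
    differences across the membrane (e.g. NH3 leaving the bacteroid
    arriving as NH4+ consumes one plant-side proton); coefficients are
    plant-side additions to the transport stoichiometry.
    """

    symbiont_metabolite: str
    plant_metabolite: str
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    plant_cofactors: dict[str, float] = field(default_factory=dict)


@dataclass
class SymbiosisSpec:
    """Coupling parameters for the nitrogen-fixing symbiosis.

    ``f`` is the symbiont mass fraction (gDW symbiont per gDW plant); all
    symbiont-internal bounds are scaled by it so symbiont fluxes are read
    per gram plant dry weight.  ``maintenance_atp`` is the symbiont's
    non-growth ATP demand in mmol·gDW(symbiont)⁻¹·day⁻¹, applied as a
    fixed lower bound on the symbiont maintenance reaction (scaled by f).
    The bacteroid is differentiated and not required to grow.
    """

    links: list[ExchangeLink]
    f: float = 0.02
    maintenance_atp: float = 0.0
    maintenance_reaction: str = ""
    prefix: str = "sym_"

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("symbiont mass fraction f must be positive")


def _prefixed(model: MetabolicModel, prefix: str) -> MetabolicModel:
    out = MetabolicModel(id=f"{prefix}{model.id}")
    for cid, name in model.compartments.items():
        out.add_compartment(prefix + cid, name)
    for met in model.metabolites.values():
        m = met.copy()
        m.id = prefix + m.id
        m.compartment = prefix + m.compartment
        out.add_metabolite(m)
    for rxn in model.reactions.values():
        r = rxn.copy()
        r.id = prefix + r.id
        r.stoichiometry = {prefix + m: c for m, c in rxn.stoichiometry.items()}
        out.add_reaction(r)
    return out


def replicate_into_tissues(model: MetabolicModel, tissues: list[str]) -> MetabolicModel:
    """Duplicate a model once per tissue with id prefixes "shoot_", ...

    GPRs are preserved; no cross-tissue stoichiometry is added here.
    """
    if len(set(tissues)) != len(tissues):
        raise ValueError(f"tissue names must be distinct: {tissues}")
    for tissue in tissues:
        for rid in model.reactions:
            if rid.startswith(tissue + "_"):
                raise ModelIntegrityError(
                    f"prefix collision: reaction {rid} already starts with {tissue}_"
                )
    combined = MetabolicModel(id=model.id + "_" + "_".join(tissues))
    for tissue in tissues:
        part = _prefixed(model, tissue + "_")
        combined.compartments.update(part.compartments)
        combined.metabolites.update(part.metabolites)
        combined.reactions.update(part.reactions)
    combined.check_integrity()
    return combined


def add_linker_reactions(
    combined: MetabolicModel, linkers: list[LinkerSpec]
) -> MetabolicModel:
    """Add one transport reaction per linker between replicated tissues."""
    seen: set[tuple[str, str, str]] = set()
    for link in linkers:
        key = (link.metabolite, link.from_tissue, link.to_tissue)
        rid = f"TL_{link.from_tissue}_{link.to_tissue}_{link.metabolite}"
        if key in seen or rid in combined.reactions:
            raise ModelIntegrityError(f"duplicate linker {key}")
        seen.add(key)
        src = f"{link.from_tissue}_{link.metabolite}"
        dst = f"{link.to_tissue}_{link.metabolite}"
        for mid in (src, dst):
            if mid not in combined.metabolites:
                raise ModelIntegrityError(f"linker metabolite {mid} not in model")
        combined.add_reaction(
            Reaction(
                rid,
                {src: -1.0, dst: +1.0},
                lower_bound=-DEFAULT_BOUND if link.reversible else 0.0,
                upper_bound=DEFAULT_BOUND,
                kind="transport",
                name=f"{link.metabolite} transporter {link.from_tissue}→{link.to_tissue}",
            )
        )
    return combined


def merge_biomass(
    combined: MetabolicModel, shoot_fraction: float,
    tissues: tuple[str, str] = ("shoot", "root"),
    growth_id: str = "BIOMASS_combined",
) -> MetabolicModel:
    """Add a combined biomass drawing α from the first tissue and 1−α
    from the second.

    Each tissue biomass reaction is rewired to *produce* one unit of a
    tissue biomass species, which the combined reaction consumes; per
    unit growth the shoot biomass flux is α and the root flux 1−α.  The
    tissue biomass reactions are retained but the objective references
    only the combined reaction.
    """
    if not 0.0 < shoot_fraction < 1.0:
        raise ValueError(f"shoot fraction must lie strictly in (0, 1): {shoot_fraction}")
    fractions = {tissues[0]: shoot_fraction, tissues[1]: 1.0 - shoot_fraction}
    stoich: dict[str, float] = {}
    for tissue, frac in fractions.items():
        biom = [
            rid
            for rid in combined.reactions
            if combined.reactions[rid].kind == "biomass" and rid.startswith(tissue + "_")
        ]
        if len(biom) != 1:
            raise ModelIntegrityError(
                f"expected exactly one biomass reaction for tissue {tissue}, got {biom}"
            )
        rid = biom[0]
        pseudo = f"{tissue}_biomass_unit"
        comp = combined.metabolites[
            next(iter(combined.reactions[rid].stoichiometry))
        ].compartment
        if pseudo not in combined.metabolites:
            combined.add_metabolite(
                Metabolite(pseudo, comp, name=f"{tissue} biomass unit")
            )
        combined.reactions[rid].stoichiometry[pseudo] = 1.0
        stoich[pseudo] = -frac
    combined.add_reaction(
        Reaction(growth_id, stoich, 0.0, DEFAULT_BOUND, kind="biomass",
                 name="combined biomass")
    )
    combined.objective = {growth_id: 1.0}
    return combined


def attach_symbiont(
    plant: MetabolicModel, symbiont: MetabolicModel, spec: SymbiosisSpec
) -> MetabolicModel:
    """Attach a bacteroid model to the (root tissue of the) plant model.

    Symbiont identifiers are prefixed (default ``sym_``), all finite
    symbiont bounds scaled by the mass fraction f, the symbiont's own
    boundary exchanges for the coupled metabolites removed, and one
    transport reaction added per :class:`ExchangeLink`.  The symbiont
    maintenance ATP demand becomes a fixed lower bound.  The symbiont's
    growth is not required.
    """
    out = plant.copy()
    sym = _prefixed(symbiont, spec.prefix)
    # scale symbiont-internal bounds to per-gDW-plant units
    for rxn in sym.reactions.values():
        rxn.lower_bound *= spec.f
        rxn.upper_bound *= spec.f
    # drop symbiont boundary exchanges now routed through the plant
    coupled = {spec.prefix + link.symbiont_metabolite for link in spec.links}
    drop = [
        rid
        for rid, rxn in sym.reactions.items()
        if rxn.kind == "exchange" and set(rxn.stoichiometry) & coupled
    ]
    sym.remove_reactions(drop, prune_metabolites=False)
    if spec.maintenance_reaction:
        mrid = spec.prefix + spec.maintenance_reaction
        if mrid not in sym.reactions:
            raise ModelIntegrityError(
                f"maintenance reaction {spec.maintenance_reaction} not in symbiont"
            )
        rxn = sym.reactions[mrid]
        rxn.lower_bound = spec.maintenance_atp * spec.f
        if rxn.upper_bound < rxn.lower_bound:
            rxn.upper_bound = rxn.lower_bound

    out.compartments.update(sym.compartments)
    for met in sym.metabolites.values():
        out.metabolites[met.id] = met
    for rxn in sym.reactions.values():
        if rxn.id in out.reactions:
            raise ModelIntegrityError(f"symbiont reaction id collision: {rxn.id}")
        out.reactions[rxn.id] = rxn

    for link in spec.links:
        sym_met = spec.prefix + link.symbiont_metabolite
        if sym_met not in out.metabolites:
            raise ModelIntegrityError(f"symbiont metabolite {sym_met} missing")
        if link.plant_metabolite not in out.metabolites:
            raise ModelIntegrityError(
                f"plant metabolite {link.plant_metabolite} missing"
            )
        stoich = {link.plant_metabolite: -1.0, sym_met: +1.0}
        for mid, coeff in link.plant_cofactors.items():
            if mid not in out.metabolites:
                raise ModelIntegrityError(f"cofactor metabolite {mid} missing")
            stoich[mid] = stoich.get(mid, 0.0) + coeff
        rid = f"TS_{link.symbiont_metabolite}"
        if rid in out.reactions:
            raise ModelIntegrityError(f"duplicate symbiosis link {rid}")
        out.add_reaction(
            Reaction(rid, stoich, link.lower_bound, link.upper_bound,
                     kind="transport",
                     name=f"plant↔symbiont {link.symbiont_metabolite} exchange")
        )
    out.id = plant.id + "+sym"
    out.check_integrity()
    return out


def apply_condition(model: MetabolicModel, condition: ConditionSpec) -> MetabolicModel:
    """Return a copy of the model with the condition's overrides applied.

    Overrides are applied atomically: an unknown reaction id raises
    before any mutation.
    """
    work = model.copy()
    condition.apply(work)
    return work
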