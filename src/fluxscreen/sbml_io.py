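"""SBML reading, writing and convention validation.

Two GPR dialects are understood on input: the structured Level-3 ``fbc``
gene-product associations, and the older COBRA convention of a
``GENE_ASSOCIATION: (A and B) or C`` line in the reaction notes.  Structured
rules win when both are present, matching how consensus-yeast-era files are
consumed in practice.

Output is a single dialect — Level 2 Version 4 with COBRA-style kinetic-law
``LOWER_BOUND``/``UPPER_BOUND`` parameters and notes-field GPRs, ``sboTerm``
attributes, and MIRIAM (identifiers.org) annotations for ChEBI and PubMed —
chosen because it round-trips every field this package models.

Unbounded fluxes are written as IEEE ``INF``/``-INF`` and recovered as such;
finite stand-ins appear only at solver hand-off, never in files.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import List, Optional

import libsbml

from .gpr import (
    BoolAnd,
    BoolOr,
    GeneRef,
    GprExpression,
    NoAssociation,
    gpr_to_string,
    parse_gpr,
)
from .model import (
    BOUNDARY_SUFFIX,
    ModelDocument,
    ModelIntegrityError,
    ReactionRecord,
    SpeciesRecord,
)

__all__ = [
    "read_sbml",
    "write_sbml",
    "validate_conventions",
    "ConventionReport",
    "SbmlFormatError",
]

_CHEBI_RE = re.compile(r"(CHEBI:\d+)")
_PUBMED_RE = re.compile(r"pubmed[/:](\d+)")
_GA_NOTE_RE = re.compile(r"GENE[ _]?ASSOCIATION\s*:\s*([^<\n]*)", re.IGNORECASE)


class SbmlFormatError(ValueError):
    """The file is not parsable SBML."""


# ---------------------------------------------------------------------------
# reading


def _notes_text(sbase) -> str:
    if not sbase.isSetNotes():
        return ""
    return sbase.getNotesString()


def _annotation_uris(sbase) -> List[str]:
    uris: List[str] = []
    for i in range(sbase.getNumCVTerms()):
        term = sbase.getCVTerm(i)
        for j in range(term.getNumResources()):
            uris.append(term.getResourceURI(j))
    return uris


def _gpr_from_fbc(assoc) -> GprExpression:
    if assoc is None:
        return NoAssociation()
    if assoc.isGeneProductRef():
        gp = assoc.getSBMLDocument().getModel().getPlugin("fbc").getGeneProduct(
            assoc.getGeneProduct()
        )
        label = gp.getLabel() if gp is not None and gp.isSetLabel() else assoc.getGeneProduct()
        return GeneRef(label)
    children = [_gpr_from_fbc(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
    children = [c for c in children if not isinstance(c, NoAssociation)]
    if not children:
        return NoAssociation()
    if len(children) == 1:
        return children[0]
    if assoc.isFbcAnd():
        return BoolAnd(tuple(children))
    return BoolOr(tuple(children))


def _read_reaction_gpr(rxn, fbc_rxn) -> GprExpression:
    # structured fbc rules take precedence; notes text is the fallback dialect
    if fbc_rxn is not None and fbc_rxn.isSetGeneProductAssociation():
        return _gpr_from_fbc(fbc_rxn.getGeneProductAssociation().getAssociation())
    m = _GA_NOTE_RE.search(_notes_text(rxn))
    if m:
        return parse_gpr(m.group(1).strip())
    return NoAssociation()


def _bound_value(x: float) -> float:
    if x <= -1e30:
        return -math.inf
    if x >= 1e30:
        return math.inf
    return x


def read_sbml(path: str) -> ModelDocument:
    """Read an SBML Level 2 or Level 3 file into a :class:`ModelDocument`.

    Bounds are taken from fbc flux-bound parameters when present, else from
    COBRA-style kinetic-law parameters.  Species whose id or name ends in
    ``_b`` (or with the SBML ``boundaryCondition`` attribute set) are flagged
    as boundary placeholders.  The objective is the fbc objective when set,
    else a reaction whose kinetic law carries ``OBJECTIVE_COEFFICIENT`` ≠ 0.
    """
    reader = libsbml.SBMLReader()
    sdoc = reader.readSBMLFromFile(path)
    if sdoc.getModel() is None or sdoc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            sdoc.getError(i).getMessage()
            for i in range(sdoc.getNumErrors())
            if sdoc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SbmlFormatError(f"cannot parse {path!r}: " + "; ".join(msgs[:3] or ["no model"]))
    model = sdoc.getModel()
    fbc = model.getPlugin("fbc")

    doc = ModelDocument(name=model.getId() or model.getName())
    known_species = set()
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        uris = _annotation_uris(sp)
        chebi = next((m.group(1) for u in uris for m in [_CHEBI_RE.search(u)] if m), None)
        rec = SpeciesRecord(
            id=sp.getId(),
            name=sp.getName(),
            compartment=sp.getCompartment(),
            chebi_id=chebi,
            sbo_term=sp.getSBOTerm() if sp.getSBOTerm() != -1 else None,
            is_boundary=sp.getId().endswith(BOUNDARY_SUFFIX)
            or sp.getName().endswith(BOUNDARY_SUFFIX)
            or sp.getBoundaryCondition(),
        )
        doc.species.append(rec)
        known_species.add(rec.id)

    objective_id: Optional[str] = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()

    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        fbc_rxn = rxn.getPlugin("fbc")
        stoich = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        unknown = sorted(set(stoich) - known_species)
        if unknown:
            raise ModelIntegrityError(
                f"reaction {rxn.getId()} references unknown species {unknown}"
            )

        lb, ub = (0.0, math.inf) if not rxn.getReversible() else (-math.inf, math.inf)
        if fbc_rxn is not None and fbc_rxn.isSetLowerFluxBound():
            p = model.getParameter(fbc_rxn.getLowerFluxBound())
            if p is not None:
                lb = _bound_value(p.getValue())
        if fbc_rxn is not None and fbc_rxn.isSetUpperFluxBound():
            p = model.getParameter(fbc_rxn.getUpperFluxBound())
            if p is not None:
                ub = _bound_value(p.getValue())
        klaw = rxn.getKineticLaw()
        if klaw is not None:
            for j in range(klaw.getNumParameters()):
                p = klaw.getParameter(j)
                if p.getId() == "LOWER_BOUND":
                    lb = _bound_value(p.getValue())
                elif p.getId() == "UPPER_BOUND":
                    ub = _bound_value(p.getValue())
                elif p.getId() == "OBJECTIVE_COEFFICIENT" and p.getValue() != 0:
                    if objective_id is None:
                        objective_id = rxn.getId()

        uris = _annotation_uris(rxn)
        pubmed = tuple(m.group(1) for u in uris for m in [_PUBMED_RE.search(u)] if m)
        doc.reactions.append(
            ReactionRecord(
                id=rxn.getId(),
                name=rxn.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=_read_reaction_gpr(rxn, fbc_rxn),
                sbo_term=rxn.getSBOTerm() if rxn.getSBOTerm() != -1 else None,
                pubmed_refs=pubmed,
            )
        )

    doc.objective_id = objective_id
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# writing


def _encode_bound(x: float) -> float:
    return x  # libsbml serialises inf as INF


def write_sbml(doc: ModelDocument, path: str) -> None:
    """Write a document as SBML L2v4 (COBRA dialect); see module docstring.

    The emitted file re-reads to an equivalent document: same ids, names,
    stoichiometry, bounds (including infinities), GPR truth tables, SBO terms
    and ChEBI/PubMed annotations.
    """
    doc.validate()
    sdoc = libsbml.SBMLDocument(2, 4)
    model = sdoc.createModel()
    model.setId(_sanitize_id(doc.name) or "model")
    model.setName(doc.name or "model")
    model.setMetaId("meta_" + (_sanitize_id(doc.name) or "model"))

    compartments = {s.compartment or "default" for s in doc.species}
    for cid in sorted(compartments):
        comp = model.createCompartment()
        comp.setId(_sanitize_id(cid))
        comp.setName(cid)
        comp.setSize(1.0)

    for s in doc.species:
        sp = model.createSpecies()
        sp.setId(s.id)
        sp.setMetaId("meta_" + s.id)
        if s.name:
            sp.setName(s.name)
        sp.setCompartment(_sanitize_id(s.compartment or "default"))
        sp.setBoundaryCondition(s.is_boundary)
        sp.setInitialAmount(0.0)
        if s.sbo_term is not None:
            sp.setSBOTerm(s.sbo_term)
        if s.chebi_id is not None:
            _add_cvterm(sp, f"http://identifiers.org/chebi/{s.chebi_id}")

    for r in doc.reactions:
        rxn = model.createReaction()
        rxn.setId(r.id)
        rxn.setMetaId("meta_" + r.id)
        if r.name:
            rxn.setName(r.name)
        rxn.setReversible(r.lower_bound < 0)
        if r.sbo_term is not None:
            rxn.setSBOTerm(r.sbo_term)
        for sid, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                ref = rxn.createReactant()
                ref.setSpecies(sid)
                ref.setStoichiometry(-coef)
            elif coef > 0:
                ref = rxn.createProduct()
                ref.setSpecies(sid)
                ref.setStoichiometry(coef)
        rule = gpr_to_string(r.gpr)
        if rule:
            rxn.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>GENE_ASSOCIATION: {rule}</p></body>"
            )
        klaw = rxn.createKineticLaw()
        klaw.setFormula("FLUX_VALUE")
        for pid, value in (
            ("LOWER_BOUND", _encode_bound(r.lower_bound)),
            ("UPPER_BOUND", _encode_bound(r.upper_bound)),
            ("OBJECTIVE_COEFFICIENT", 1.0 if r.id == doc.objective_id else 0.0),
            ("FLUX_VALUE", 0.0),
        ):
            p = klaw.createParameter()
            p.setId(pid)
            p.setValue(value)
        for pm in r.pubmed_refs:
            _add_cvterm(rxn, f"http://identifiers.org/pubmed/{pm}")

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(sdoc, path):
        raise IOError(f"failed to write SBML to {path!r}")


def _sanitize_id(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", text or "")


def _add_cvterm(sbase, uri: str) -> None:
    term = libsbml.CVTerm()
    term.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
    term.setBiologicalQualifierType(libsbml.BQB_IS)
    term.addResource(uri)
    sbase.addCVTerm(term)


# ---------------------------------------------------------------------------
# conventions


@dataclass
class ConventionReport:
    """Outcome of checking a document against the consensus-yeast encoding
    conventions.  An empty report means the document conforms."""

    reversible_isa: List[str] = field(default_factory=list)
    malformed_exchanges: List[str] = field(default_factory=list)
    boundary_in_internal: List[str] = field(default_factory=list)
    missing_sbo: bool = False

    @property
    def violations(self) -> List[str]:
        out = [f"isa reaction {rid} is reversible (lower bound < 0)" for rid in self.reversible_isa]
        out += [
            f"exchange-like reaction {rid} is not of single-internal-species form"
            for rid in self.malformed_exchanges
        ]
        out += [
            f"boundary species {sid} participates in non-exchange reaction {rid}"
            for sid, rid in self.boundary_in_internal
        ]
        if self.missing_sbo:
            out.append(
                "no SBO terms anywhere: reconstruction derivation cannot distinguish "
                "evidence from modelling assumptions"
            )
        return out

    def __bool__(self) -> bool:
        return bool(self.violations)


def validate_conventions(doc: ModelDocument) -> ConventionReport:
    """Report every departure from the model-encoding conventions.

    Checks: irreversibility of isa reactions, single-internal-species form of
    any reaction touching a boundary placeholder, confinement of boundary
    species to exchange reactions, and presence of at least one SBO term
    (without which a reconstruction cannot be derived).
    """
    report = ConventionReport()
    boundary = {s.id for s in doc.species if s.is_boundary}
    for r in doc.reactions:
        if r.is_isa and r.lower_bound < 0:
            report.reversible_isa.append(r.id)
        touches_boundary = any(sid in boundary for sid in r.stoichiometry)
        if touches_boundary and not doc.is_exchange(r):
            report.malformed_exchanges.append(r.id)
            for sid in r.stoichiometry:
                if sid in boundary:
                    report.boundary_in_internal.append((sid, r.id))
    has_sbo = any(r.sbo_term is not None for r in doc.reactions) or any(
        s.sbo_term is not None for s in doc.species
    )
    report.missing_sbo = not has_sbo
    return report
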