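"""In-memory representation of a stoichiometrically constrained metabolic network.

A :class:`ModelDocument` holds species, reactions (with bounds and GPR rules)
and an objective reaction, and is the container every other module consumes.
The stoichiometric matrix S is reconstructible from the reactions alone:
rows are non-boundary species, columns are reactions, and a steady state is
any flux vector v with S v = 0 inside the bounds.

Conventions follow the consensus-yeast encoding: boundary placeholder species
carry an ``_b`` identifier suffix and are excluded from S; exchange reactions
touch exactly one non-boundary species with coefficient −1, so positive flux
exports the compound and negative flux imports it; "isa" encapsulating
reactions carry SBO:395 and model-only (biomass, evidence-free transport)
reactions carry SBO:397.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .gpr import GprExpression, NoAssociation

__all__ = [
    "SpeciesRecord",
    "ReactionRecord",
    "ModelDocument",
    "ModelIntegrityError",
    "SBO_ENCAPSULATING",
    "SBO_OMITTED",
    "stoichiometric_matrix",
]

#: SBO term for encapsulating ("isa") processes mapping specific to generic species.
SBO_ENCAPSULATING = 395
#: SBO term for omitted processes (biomass, hypothetical transport).
SBO_OMITTED = 397

BOUNDARY_SUFFIX = "_b"


class ModelIntegrityError(ValueError):
    """A document violates a structural invariant (duplicate ids, unknown
    species references, inverted bounds, missing objective)."""


@dataclass
class SpeciesRecord:
    id: str
    name: str = ""
    compartment: str = ""
    chebi_id: Optional[str] = None
    sbo_term: Optional[int] = None
    is_boundary: bool = False


@dataclass
class ReactionRecord:
    id: str
    name: str = ""
    #: species id -> signed coefficient; negative = consumed, positive = produced
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -math.inf
    upper_bound: float = math.inf
    gpr: GprExpression = field(default_factory=NoAssociation)
    sbo_term: Optional[int] = None
    pubmed_refs: Tuple[str, ...] = ()

    @property
    def is_isa(self) -> bool:
        return self.sbo_term == SBO_ENCAPSULATING

    @property
    def is_omitted(self) -> bool:
        return self.sbo_term == SBO_OMITTED

    def copy(self) -> "ReactionRecord":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class ModelDocument:
    species: List[SpeciesRecord] = field(default_factory=list)
    reactions: List[ReactionRecord] = field(default_factory=list)
    objective_id: Optional[str] = None
    name: str = ""
    notes: Dict[str, str] = field(default_factory=dict)

    # -- lookups ----------------------------------------------------------

    def species_by_id(self) -> Dict[str, SpeciesRecord]:
        return {s.id: s for s in self.species}

    def reactions_by_id(self) -> Dict[str, ReactionRecord]:
        return {r.id: r for r in self.reactions}

    def reaction(self, rid: str) -> ReactionRecord:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def genes(self) -> frozenset:
        """Exactly the set of gene leaves across all GPR rules."""
        out: set = set()
        for r in self.reactions:
            out |= r.gpr.genes()
        return frozenset(out)

    # -- derived structure -------------------------------------------------

    def is_exchange(self, rxn: ReactionRecord) -> bool:
        """True iff the reaction touches exactly one non-boundary species;
        any other participants are ``_b`` placeholders outside S, so the
        reaction is a net source/sink of that one compound."""
        boundary = {s.id for s in self.species if s.is_boundary}
        internal = [sid for sid in rxn.stoichiometry if sid not in boundary]
        return len(internal) == 1

    def exchange_reactions(self) -> List[ReactionRecord]:
        return [r for r in self.reactions if self.is_exchange(r)]

    def exchanged_species(self, rxn: ReactionRecord) -> str:
        """The single internal species moved by an exchange reaction."""
        boundary = {s.id for s in self.species if s.is_boundary}
        internal = [sid for sid in rxn.stoichiometry if sid not in boundary]
        if len(internal) != 1:
            raise ValueError(f"{rxn.id} is not an exchange reaction")
        return internal[0]

    def copy(self) -> "ModelDocument":
        return ModelDocument(
            species=[replace(s) for s in self.species],
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            name=self.name,
            notes=dict(self.notes),
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ModelIntegrityError` on any structural violation."""
        problems: List[str] = []
        sids = [s.id for s in self.species]
        if len(sids) != len(set(sids)):
            dup = sorted({x for x in sids if sids.count(x) > 1})
            problems.append(f"duplicate species ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            dup = sorted({x for x in rids if rids.count(x) > 1})
            problems.append(f"duplicate reaction ids: {dup}")
        known = set(sids)
        for r in self.reactions:
            unknown = sorted(set(r.stoichiometry) - known)
            if unknown:
                problems.append(f"reaction {r.id} references unknown species {unknown}")
            if r.lower_bound > r.upper_bound:
                problems.append(
                    f"reaction {r.id} has lower_bound {r.lower_bound} > upper_bound {r.upper_bound}"
                )
        if self.objective_id is not None and self.objective_id not in set(rids):
            problems.append(f"objective reaction {self.objective_id!r} not in document")
        if problems:
            raise ModelIntegrityError("; ".join(problems))


def stoichiometric_matrix(
    doc: ModelDocument,
) -> Tuple[np.ndarray, List[str], List[str]]:
    """Build S with one row per non-boundary species and one column per reaction.

    Returns ``(S, species_ids, reaction_ids)``.  Boundary placeholder species
    never reach the solver: their rows are simply absent, which is what turns
    an exchange reaction into a net source/sink.
    """
    internal = [s.id for s in doc.species if not s.is_boundary]
    row = {sid: i for i, sid in enumerate(internal)}
    rids = [r.id for r in doc.reactions]
    S = np.zeros((len(internal), len(rids)))
    for j, r in enumerate(doc.reactions):
        for sid, coef in r.stoichiometry.items():
            i = row.get(sid)
            if i is not None:
                S[i, j] += coef
    return S, internal, rids
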