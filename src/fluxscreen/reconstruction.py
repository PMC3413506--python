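"""Deriving an evidence-only reconstruction (GENRE) from a model (GEM),
and detecting blocked reactions.

A GEM carries modelling assumptions a reconstruction must not: encapsulating
"isa" reactions (SBO:395) that funnel specific compounds into generic class
species, omitted-process reactions (SBO:397) such as biomass production and
hypothetical transport, and directionality bounds.  Derivation strips all
three, leaving only the evidence-backed network; it is idempotent.

A blocked reaction is one that cannot carry flux under any feasible steady
state for a given exchange regime — a connectivity gap marker.
"""

from __future__ import annotations

import math
from typing import Optional, Set, Tuple

from .fba import DEFAULT_BIG_BOUND, flux_variability
from .model import (
    ModelDocument,
    SBO_ENCAPSULATING,
    SBO_OMITTED,
)
from .perturb import MediumSpec, apply_medium

__all__ = ["derive_reconstruction", "blocked_reactions", "all_open_medium"]


def derive_reconstruction(doc: ModelDocument) -> ModelDocument:
    """Strip modelling assumptions from a GEM, returning the GENRE.

    Removes every reaction annotated SBO:395 (encapsulating process) or
    SBO:397 (omitted process); lifts all remaining bounds to (−inf, +inf);
    prunes species — boundary placeholders and modelling species such as
    "biomass" included — that no longer participate in any reaction.  The
    result carries ``notes["is_reconstruction"]`` and no objective.

    A document with no SBO annotation at all raises ``ValueError``: the
    derivation would be the identity, which almost surely means the model
    was never marked up rather than that it contains no assumptions.
    """
    has_sbo = any(r.sbo_term is not None for r in doc.reactions) or any(
        s.sbo_term is not None for s in doc.species
    )
    # deriving twice is the identity: a document already flagged as a
    # reconstruction legitimately carries no assumption markers
    if not has_sbo and doc.notes.get("is_reconstruction") != "true":
        raise ValueError(
            "document carries no SBO terms; cannot distinguish evidence from "
            "modelling assumptions"
        )
    out = doc.copy()
    out.reactions = [
        r
        for r in out.reactions
        if r.sbo_term not in (SBO_ENCAPSULATING, SBO_OMITTED)
    ]
    for r in out.reactions:
        r.lower_bound = -math.inf
        r.upper_bound = math.inf
    used = set()
    for r in out.reactions:
        used |= set(r.stoichiometry)
    out.species = [s for s in out.species if s.id in used]
    out.objective_id = None
    out.notes["is_reconstruction"] = "true"
    return out


def all_open_medium(doc: ModelDocument, magnitude: float = DEFAULT_BIG_BOUND) -> MediumSpec:
    """Every exchange reaction open to both uptake and export."""
    return MediumSpec(
        bounds={r.id: (-magnitude, magnitude) for r in doc.exchange_reactions()},
        name="all-open",
    )


def blocked_reactions(
    doc: ModelDocument,
    medium: Optional[MediumSpec] = None,
    tol: float = 1e-7,
) -> Tuple[Set[str], float]:
    """Reactions that cannot carry flux, and their fraction of all reactions.

    A reaction is blocked iff its flux-variability range is (0, 0) with the
    objective unconstrained, under the given exchange regime.  The default
    regime opens every exchange reaction in both directions, so blockage
    reflects network gaps rather than medium choices; pass a medium to ask
    the condition-specific question instead.
    """
    regime = medium if medium is not None else all_open_medium(doc)
    work = apply_medium(doc, regime)
    var = flux_variability(work, objective_fraction=0.0)
    blocked = {
        rid
        for rid, (lo, hi) in var.ranges.items()
        if abs(lo) <= tol and abs(hi) <= tol
    }
    fraction = len(blocked) / len(doc.reactions) if doc.reactions else 0.0
    return blocked, fraction
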