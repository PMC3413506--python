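"""Perturbations: media, gene deletions, anaerobiosis, fractional flux limits.

Every operation returns a modified copy of the document — the input is never
touched — so perturbations compose and screens stay order-independent.

Sign convention (from the exchange encoding): negative exchange flux imports
a compound, positive exports it.  "Closing a medium component" therefore
means raising that exchange reaction's lower bound to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set, Tuple

from .fba import DEFAULT_BIG_BOUND, FluxSolution
from .gpr import GprExpression
from .model import ModelDocument, ReactionRecord

__all__ = [
    "MediumSpec",
    "PerturbationSet",
    "AnaerobicSpec",
    "evaluate_gpr",
    "apply_deletions",
    "apply_medium",
    "anaerobic_transform",
    "restrict_gene_flux",
    "apply_perturbation",
    "supplemented_medium",
    "read_medium_tsv",
    "write_medium_tsv",
]

#: default uptake magnitude when a medium component is opened without an
#: explicit bound (COBRA convention)
DEFAULT_UPTAKE = DEFAULT_BIG_BOUND


@dataclass
class MediumSpec:
    """Growth medium: exchange-reaction bounds, in flux units.

    Unlisted exchange reactions are closed to uptake (lower bound 0) but left
    open to export when the medium is applied.
    """

    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    name: str = "medium"


@dataclass
class PerturbationSet:
    """A joint genetic perturbation: hard deletions plus fractional flux
    restrictions (gene -> fraction of reference flux retained)."""

    deleted_genes: Set[str] = field(default_factory=set)
    flux_restrictions: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        bad = {g: f for g, f in self.flux_restrictions.items() if not 0 <= f <= 1}
        if bad:
            raise ValueError(f"restriction fractions outside [0, 1]: {bad}")


def evaluate_gpr(gpr: GprExpression, deleted: Set[str]) -> bool:
    """True iff the reaction retains a catalyst after deleting ``deleted``."""
    return gpr.evaluate(deleted)


def apply_deletions(doc: ModelDocument, genes: Iterable[str]) -> ModelDocument:
    """Knock out genes: any reaction whose GPR evaluates false gets bounds
    (0, 0).  Unknown gene ids warn and are otherwise inert."""
    genes = set(genes)
    unknown = genes - doc.genes
    if unknown:
        warnings.warn(f"genes not in model, ignored by GPR logic: {sorted(unknown)}")
    out = doc.copy()
    for r in out.reactions:
        if not r.gpr.evaluate(genes):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


def apply_medium(doc: ModelDocument, medium: MediumSpec) -> ModelDocument:
    """Impose a medium: listed exchange bounds are replaced verbatim; every
    other exchange reaction keeps its export capacity but loses uptake.

    Raises ``KeyError`` for ids absent from the document and ``ValueError``
    for ids that are not exchange reactions.  Idempotent for a fixed medium.
    """
    by_id = doc.reactions_by_id()
    for rid in medium.bounds:
        if rid not in by_id:
            raise KeyError(f"medium refers to unknown reaction {rid!r}")
        if not doc.is_exchange(by_id[rid]):
            raise ValueError(f"medium component {rid!r} is not an exchange reaction")
    out = doc.copy()
    for r in out.reactions:
        if not out.is_exchange(r):
            continue
        if r.id in medium.bounds:
            r.lower_bound, r.upper_bound = medium.bounds[r.id]
        else:
            r.lower_bound = max(r.lower_bound, 0.0)
    return out


def supplemented_medium(
    doc: ModelDocument, uptake: float = DEFAULT_UPTAKE, name: str = "supplemented"
) -> MediumSpec:
    """A maximal medium: every exchange reaction open to uptake at ``uptake``
    flux units (and unrestricted export) — the rescue condition of an
    auxotrophy screen."""
    bounds = {
        r.id: (-uptake, max(r.upper_bound, uptake)) for r in doc.exchange_reactions()
    }
    return MediumSpec(bounds=bounds, name=name)


@dataclass
class AnaerobicSpec:
    """Names the reactions an anaerobic shift must touch.

    The shift closes oxygen uptake, opens uptake of the four compounds yeast
    must be given when grown strictly anaerobically (ergosterol, lanosterol,
    zymosterol, phosphatidate), and swaps the lipid pseudoreaction so the
    biomass definition no longer requires the two oxygen-dependent sterols.
    """

    oxygen_exchange: str = ""
    supplement_exchanges: Tuple[str, ...] = ()
    aerobic_lipid: str = ""
    anaerobic_lipid: str = ""
    supplement_uptake: float = DEFAULT_UPTAKE

    #: species-name fragments used to locate reactions when ids are not given
    SUPPLEMENT_PATTERNS = ("ergosterol", "lanosterol", "zymosterol", "phosphatidate")
    OXYGEN_PATTERN = "oxygen"


def _find_exchange_by_species_name(doc: ModelDocument, pattern: str) -> Optional[str]:
    species = doc.species_by_id()
    for r in doc.exchange_reactions():
        sid = doc.exchanged_species(r)
        label = (species[sid].name or sid).lower()
        if pattern in label:
            return r.id
    return None


def anaerobic_transform(
    doc: ModelDocument, spec: Optional[AnaerobicSpec] = None
) -> ModelDocument:
    """Shift a model to anaerobiosis; see :class:`AnaerobicSpec`.

    Reactions are located by the ids in ``spec`` when given, else by matching
    exchange-species names against the standard patterns and lipid
    pseudoreaction names against "lipid".  Anything that cannot be located is
    reported in one error, since a partial shift would silently simulate the
    wrong condition.
    """
    spec = spec or AnaerobicSpec()
    by_id = doc.reactions_by_id()
    missing = []

    oxygen = spec.oxygen_exchange or _find_exchange_by_species_name(
        doc, AnaerobicSpec.OXYGEN_PATTERN
    )
    if oxygen is None or oxygen not in by_id:
        missing.append("oxygen exchange")

    supplements = list(spec.supplement_exchanges)
    if not supplements:
        for pat in AnaerobicSpec.SUPPLEMENT_PATTERNS:
            rid = _find_exchange_by_species_name(doc, pat)
            if rid is None:
                missing.append(f"{pat} exchange")
            else:
                supplements.append(rid)
    else:
        missing.extend(f"supplement exchange {rid}" for rid in supplements if rid not in by_id)

    def locate_lipid(explicit: str, tag: str) -> Optional[str]:
        if explicit:
            return explicit if explicit in by_id else None
        hits = [
            r.id
            for r in doc.reactions
            if tag in (r.name or r.id).lower() and "lipid" in (r.name or r.id).lower()
        ]
        return hits[0] if hits else None

    aerobic_lipid = locate_lipid(spec.aerobic_lipid, "aerobic")
    anaerobic_lipid = locate_lipid(spec.anaerobic_lipid, "anaerobic")
    # "anaerobic" contains "aerobic": disambiguate when both matched the same
    if aerobic_lipid == anaerobic_lipid and aerobic_lipid is not None:
        aerobic_lipid = None
    if aerobic_lipid is None:
        candidates = [
            r.id
            for r in doc.reactions
            if "lipid" in (r.name or r.id).lower()
            and "anaerobic" not in (r.name or r.id).lower()
            and not doc.is_exchange(r)
        ]
        aerobic_lipid = candidates[0] if candidates else None
    if aerobic_lipid is None:
        missing.append("aerobic lipid pseudoreaction")
    if anaerobic_lipid is None:
        missing.append("anaerobic lipid pseudoreaction")

    if missing:
        raise KeyError(
            "anaerobic transform could not locate: " + ", ".join(missing)
        )

    out = doc.copy()
    by_id = out.reactions_by_id()
    by_id[oxygen].lower_bound = max(by_id[oxygen].lower_bound, 0.0)
    for rid in supplements:
        r = by_id[rid]
        r.lower_bound = min(r.lower_bound, -spec.supplement_uptake)
    by_id[aerobic_lipid].lower_bound = 0.0
    by_id[aerobic_lipid].upper_bound = 0.0
    ana = by_id[anaerobic_lipid]
    if ana.upper_bound <= 0:
        ana.upper_bound = math.inf
    ana.lower_bound = max(ana.lower_bound, 0.0)
    return out


def restrict_gene_flux(
    doc: ModelDocument,
    gene: str,
    fraction: float,
    reference: FluxSolution,
    sign_preserving: bool = False,
) -> ModelDocument:
    """Limit every reaction carrying ``gene`` in its GPR to a fraction of its
    reference (wild-type geometric FBA) flux.

    Default mode intersects bounds with the symmetric band
    [-f·|v*|, +f·|v*|]; ``sign_preserving=True`` instead restricts to the
    interval between 0 and f·v*, forbidding reversal of the reference
    direction.  ``fraction=0`` equals deleting the gene's reactions;
    ``fraction=1`` never loosens existing bounds.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if gene not in doc.genes:
        warnings.warn(f"gene {gene!r} not in model; restriction is a no-op")
        return doc.copy()
    out = doc.copy()
    for r in out.reactions:
        if gene not in r.gpr.genes():
            continue
        v_ref = reference.fluxes.get(r.id, 0.0)
        if sign_preserving:
            lo, hi = (0.0, fraction * v_ref) if v_ref >= 0 else (fraction * v_ref, 0.0)
        else:
            band = fraction * abs(v_ref)
            lo, hi = -band, band
        r.lower_bound = max(r.lower_bound, lo)
        r.upper_bound = min(r.upper_bound, hi)
    return out


def apply_perturbation(
    doc: ModelDocument,
    perturbation: PerturbationSet,
    reference: Optional[FluxSolution] = None,
    sign_preserving: bool = False,
) -> ModelDocument:
    """Apply deletions and flux restrictions jointly.

    A reaction annotated to several restricted genes is restricted once per
    gene with identical bands, which is idempotent — bounds are set, not
    multiplied.
    """
    out = apply_deletions(doc, perturbation.deleted_genes) if perturbation.deleted_genes else doc.copy()
    if perturbation.flux_restrictions:
        if reference is None:
            raise ValueError("flux restrictions require a reference flux solution")
        for gene, fraction in sorted(perturbation.flux_restrictions.items()):
            out = restrict_gene_flux(out, gene, fraction, reference, sign_preserving)
    return out


def read_medium_tsv(path: str, name: Optional[str] = None) -> MediumSpec:
    """Read a medium from TSV: ``exchange_id<TAB>lower<TAB>upper`` per line,
    ``#`` comments allowed; ``-inf``/``inf`` accepted."""
    bounds = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, lo, hi = line.split("\t")
            bounds[rid] = (float(lo), float(hi))
    return MediumSpec(bounds=bounds, name=name or path)


def write_medium_tsv(medium: MediumSpec, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# medium: {medium.name}\n")
        for rid, (lo, hi) in sorted(medium.bounds.items()):
            fh.write(f"{rid}\t{lo}\t{hi}\n")
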