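"""Synthetic models with analytically known behaviour.

Every generator returns a :class:`~fluxscreen.model.ModelDocument` that
passes the encoding-convention checks and whose optima are hand-derivable,
so the whole toolchain — parser, solver, screens, derivation — is testable
without downloading any genome-scale file.

Generators
----------
``make_chain_fixture``
    A linear uptake → ... → biomass chain, unit stoichiometry, one gene per
    enzymatic step.  FBA optimum equals the uptake bound; restricting any
    gene to a fraction f of wild type scales the optimum by exactly f, and a
    serial gene pair restricted to f has epistasis f − f² (+0.25 at f=0.5).
``make_two_branch_fixture``
    Two independent demand branches, each with a gene-bearing reaction in
    parallel to an unannotated one.  The spare capacity absorbs any single
    or joint restriction, so every gene pair has epistasis exactly 0.
``make_branched_fixture``
    The kitchen-sink model: isoenzyme redundancy, an AND-gated cofactor
    loop, "isa" encapsulation feeding a generic lipid class, aerobic and
    anaerobic lipid pseudoreactions, oxygen-dependent sterol synthesis, and
    a supplementable amino-acid auxotrophy — the yeast-model logic at toy
    scale.
``make_random_feasible``
    Seeded random networks built around a strictly feasible flux vector, so
    the optimum is guaranteed nonzero and small enough for the
    vertex-enumeration oracle.
``make_multigene_fixture``
    Many parallel two-step branches with random capacities, for desk-scale
    pairwise epistasis screens: same-branch pairs interact positively,
    cross-branch pairs negatively, with analytic magnitudes.
"""

from __future__ import annotations

import math
from typing import Dict, Optional

import numpy as np

from .gpr import BoolAnd, BoolOr, GeneRef, NoAssociation, parse_gpr
from .model import (
    ModelDocument,
    ReactionRecord,
    SBO_ENCAPSULATING,
    SBO_OMITTED,
    SpeciesRecord,
)

__all__ = [
    "make_chain_fixture",
    "make_two_branch_fixture",
    "make_branched_fixture",
    "make_random_feasible",
    "make_multigene_fixture",
    "FIXTURES",
]

_CELL = "cell"
_ENV = "env"


def _species(doc: ModelDocument, sid: str, name: str = "", boundary: bool = False) -> None:
    doc.species.append(
        SpeciesRecord(
            id=sid,
            name=name or sid,
            compartment=_ENV if boundary else _CELL,
            is_boundary=boundary,
        )
    )


def _exchange(
    doc: ModelDocument,
    rid: str,
    sid: str,
    lb: float,
    ub: float,
    name: str = "",
) -> None:
    """Exchange reaction 'sid ->' with a _b placeholder product: internal
    species coefficient −1, so positive flux exports and negative imports."""
    placeholder = sid + "_b"
    if placeholder not in {s.id for s in doc.species}:
        _species(doc, placeholder, boundary=True)
    doc.reactions.append(
        ReactionRecord(
            id=rid,
            name=name or f"{sid} exchange",
            stoichiometry={sid: -1.0, placeholder: 1.0},
            lower_bound=lb,
            upper_bound=ub,
            sbo_term=SBO_OMITTED,
        )
    )


def make_chain_fixture(length: int = 3, uptake_bound: float = 10.0) -> ModelDocument:
    """Linear chain with ``length`` internal metabolites M1..Mn, a gene G_i on
    each conversion step, and a biomass drain.  FBA optimum = ``uptake_bound``."""
    if length < 2:
        raise ValueError("chain length must be >= 2")
    doc = ModelDocument(name=f"chain{length}")
    for i in range(1, length + 1):
        _species(doc, f"M{i}")
    _species(doc, "bio", "biomass")
    _exchange(doc, "EX_M1", "M1", -uptake_bound, 0.0, "nutrient exchange")
    for i in range(1, length):
        doc.reactions.append(
            ReactionRecord(
                id=f"R{i}",
                name=f"step {i}",
                stoichiometry={f"M{i}": -1.0, f"M{i+1}": 1.0},
                lower_bound=0.0,
                gpr=GeneRef(f"G{i}"),
            )
        )
    doc.reactions.append(
        ReactionRecord(
            id="growth",
            name="biomass pseudoreaction",
            stoichiometry={f"M{length}": -1.0, "bio": 1.0},
            lower_bound=0.0,
            sbo_term=SBO_OMITTED,
        )
    )
    _exchange(doc, "EX_bio", "bio", 0.0, math.inf, "biomass exchange")
    doc.objective_id = "EX_bio"
    doc.validate()
    return doc


def make_two_branch_fixture(uptake_bound: float = 10.0) -> ModelDocument:
    """Two independent branches with spare unannotated capacity.

    Biomass needs P1 and P2 in equal measure; each is made from A either by a
    gene-bearing reaction (gx on branch 1, gy on branch 2) or by an
    unannotated isozyme-free route.  Restricting gx and/or gy to any
    fraction of the (evenly split) reference flux leaves the optimum at
    ``uptake_bound``/2, so epsilon(gx, gy) = 0 exactly.
    """
    doc = ModelDocument(name="two_branch")
    for sid in ("A", "P1", "P2", "bio"):
        _species(doc, sid)
    _exchange(doc, "EX_A", "A", -uptake_bound, 0.0, "nutrient exchange")
    for branch, gene in (("1", "gx"), ("2", "gy")):
        doc.reactions.append(
            ReactionRecord(
                id=f"R{branch}g",
                name=f"branch {branch} (annotated)",
                stoichiometry={"A": -1.0, f"P{branch}": 1.0},
                lower_bound=0.0,
                gpr=GeneRef(gene),
            )
        )
        doc.reactions.append(
            ReactionRecord(
                id=f"R{branch}o",
                name=f"branch {branch} (spare)",
                stoichiometry={"A": -1.0, f"P{branch}": 1.0},
                lower_bound=0.0,
            )
        )
    doc.reactions.append(
        ReactionRecord(
            id="growth",
            name="biomass pseudoreaction",
            stoichiometry={"P1": -1.0, "P2": -1.0, "bio": 1.0},
            lower_bound=0.0,
            sbo_term=SBO_OMITTED,
        )
    )
    _exchange(doc, "EX_bio", "bio", 0.0, math.inf, "biomass exchange")
    doc.objective_id = "EX_bio"
    doc.validate()
    return doc


def make_branched_fixture(uptake_bound: float = 10.0) -> ModelDocument:
    """Toy model exercising every modelling idiom the screens rely on.

    Glucose is assimilated by either of two isoenzyme-annotated parallel
    reactions (GOR1, GOR2).  Conversion to the central precursor B consumes
    a cofactor regenerated by an AND-gated complex (GC1 and GC2).  B feeds
    four demands: biomass directly; alanine (GAux — rescuable by uptake,
    i.e. an auxotrophy when deleted); two specific sphingolipids (GL1, GL2)
    encapsulated into a generic class by irreversible isa reactions; and
    oxygen-dependent sterol synthesis (GS).  The aerobic lipid pseudoreaction
    combines sphingolipid class + sterol into "lipid"; the anaerobic variant
    (shipped closed) substitutes imported ergosterol for the oxygen-dependent
    sterol.  Biomass = B + alanine + lipid.

    Wild-type aerobic optimum: ``uptake_bound``/4 (four units of B per unit
    biomass).  After the anaerobic transform: ``uptake_bound``/3.
    """
    doc = ModelDocument(name="branched")
    internal = {
        "glc": "glucose",
        "A": "intermediate A",
        "B": "precursor B",
        "cof": "cofactor (charged)",
        "cofH": "cofactor (spent)",
        "sphA": "sphingolipid A",
        "sphB": "sphingolipid B",
        "sphcls": "complex sphingolipid",
        "sterol": "endogenous sterol",
        "ergo": "ergosterol",
        "lano": "lanosterol",
        "zymo": "zymosterol",
        "pa": "phosphatidate",
        "ala": "L-alanine",
        "o2": "oxygen",
        "lipid": "lipid",
        "bio": "biomass",
    }
    for sid, name in internal.items():
        _species(doc, sid, name)

    _exchange(doc, "EX_glc", "glc", -uptake_bound, 0.0, "glucose exchange")
    _exchange(doc, "EX_o2", "o2", -math.inf, 0.0, "oxygen exchange")
    _exchange(doc, "EX_ergo", "ergo", 0.0, math.inf, "ergosterol exchange")
    _exchange(doc, "EX_lano", "lano", 0.0, math.inf, "lanosterol exchange")
    _exchange(doc, "EX_zymo", "zymo", 0.0, math.inf, "zymosterol exchange")
    _exchange(doc, "EX_pa", "pa", 0.0, math.inf, "phosphatidate exchange")
    _exchange(doc, "EX_ala", "ala", 0.0, math.inf, "L-alanine exchange")
    _exchange(doc, "EX_bio", "bio", 0.0, math.inf, "biomass exchange")

    def rxn(rid, name, stoich, gpr=None, sbo=None, lb=0.0, ub=math.inf):
        doc.reactions.append(
            ReactionRecord(
                id=rid, name=name, stoichiometry=stoich,
                lower_bound=lb, upper_bound=ub,
                gpr=gpr or NoAssociation(), sbo_term=sbo,
            )
        )

    rxn("ALT1", "glucose assimilation I", {"glc": -1.0, "A": 1.0}, GeneRef("GOR1"))
    rxn("ALT2", "glucose assimilation II", {"glc": -1.0, "A": 1.0}, GeneRef("GOR2"))
    rxn(
        "CENT", "central conversion",
        {"A": -1.0, "cof": -1.0, "B": 1.0, "cofH": 1.0},
        GeneRef("GB"),
    )
    rxn(
        "COFREG", "cofactor regeneration",
        {"cofH": -1.0, "cof": 1.0},
        BoolAnd((GeneRef("GC1"), GeneRef("GC2"))),
    )
    rxn("SPH1", "sphingolipid A synthesis", {"B": -1.0, "sphA": 1.0}, GeneRef("GL1"))
    rxn("SPH2", "sphingolipid B synthesis", {"B": -1.0, "sphB": 1.0}, GeneRef("GL2"))
    rxn("ISA1", "sphA isa complex sphingolipid", {"sphA": -1.0, "sphcls": 1.0},
        sbo=SBO_ENCAPSULATING)
    rxn("ISA2", "sphB isa complex sphingolipid", {"sphB": -1.0, "sphcls": 1.0},
        sbo=SBO_ENCAPSULATING)
    rxn("STS", "sterol synthesis (oxygen-dependent)",
        {"B": -1.0, "o2": -1.0, "sterol": 1.0}, GeneRef("GS"))
    rxn("ALAS", "alanine synthesis", {"B": -1.0, "ala": 1.0}, GeneRef("GAux"))
    rxn("LIPA", "aerobic lipid pseudoreaction",
        {"sphcls": -1.0, "sterol": -1.0, "lipid": 1.0}, sbo=SBO_OMITTED)
    rxn("LIPN", "anaerobic lipid pseudoreaction",
        {"sphcls": -1.0, "ergo": -1.0, "lipid": 1.0}, sbo=SBO_OMITTED, ub=0.0)
    rxn("GROWTH", "biomass pseudoreaction",
        {"B": -1.0, "ala": -1.0, "lipid": -1.0, "bio": 1.0}, sbo=SBO_OMITTED)

    doc.objective_id = "EX_bio"
    doc.validate()
    return doc


#: gene lists matching :func:`make_branched_fixture` phenotypes
BRANCHED_ESSENTIAL = frozenset({"GB", "GC1", "GC2", "GS"})
BRANCHED_AUXOTROPHIC = frozenset({"GAux"})


def make_random_feasible(
    seed: int, n_species: int = 4, n_reactions: int = 8
) -> ModelDocument:
    """Seeded random network with a guaranteed nonzero optimum.

    A backbone chain (uptake → M1 → ... → Mn → export) is strictly feasible
    at the uptake bound with every extra reaction idle, so the optimum is at
    least the uptake bound; extra reactions with random stoichiometry and
    bounds may only raise it.  Reaction count stays small enough for the
    vertex-enumeration oracle.  Identical seeds give identical documents.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    backbone = n_species + 1  # uptake + (n_species - 1) steps + export
    if n_reactions < backbone:
        raise ValueError(f"need at least {backbone} reactions for the backbone")
    rng = np.random.default_rng(seed)
    uptake = float(np.round(rng.uniform(5.0, 15.0), 3))
    doc = ModelDocument(name=f"random{seed}")
    for i in range(1, n_species + 1):
        _species(doc, f"M{i}")
    _exchange(doc, "EX_in", "M1", -uptake, 0.0, "nutrient exchange")
    for i in range(1, n_species):
        doc.reactions.append(
            ReactionRecord(
                id=f"R{i}",
                name=f"step {i}",
                stoichiometry={f"M{i}": -1.0, f"M{i+1}": 1.0},
                lower_bound=0.0,
                gpr=GeneRef(f"G{i}"),
            )
        )
    _exchange(doc, "EX_out", f"M{n_species}", 0.0, math.inf, "product exchange")
    for k in range(n_reactions - backbone):
        i, j = rng.choice(n_species, size=2, replace=False) + 1
        a = float(rng.integers(1, 3))
        b = float(rng.integers(1, 3))
        reversible = bool(rng.random() < 0.3)
        cap = float(np.round(rng.uniform(1.0, 10.0), 3))
        doc.reactions.append(
            ReactionRecord(
                id=f"X{k}",
                name=f"extra {k}",
                stoichiometry={f"M{i}": -a, f"M{j}": b},
                lower_bound=-cap if reversible else 0.0,
                upper_bound=cap,
                gpr=GeneRef(f"GX{k}"),
            )
        )
    doc.objective_id = "EX_out"
    doc.validate()
    return doc


def make_multigene_fixture(
    n_genes: int = 100, seed: int = 0
) -> ModelDocument:
    """Parallel two-step branches for desk-scale epistasis screens.

    ``n_genes``/2 branches run hub → I_k → product, the first step annotated
    with gene ``G<k>a`` and capacity c_k, the second with ``G<k>b``.  Uptake
    exceeds total capacity, so every branch saturates: the wild-type optimum
    is Σc_k and each branch's reference flux is its own c_k (unique, no
    centring ambiguity).  Under restriction to fraction f, a same-branch
    pair has epsilon = a(1−a) > 0 with a = (1−f)·c_k/Σc, and a cross-branch
    pair epsilon = −a·b < 0 — both signs present, magnitudes analytic.
    """
    if n_genes < 2 or n_genes % 2:
        raise ValueError("n_genes must be an even number >= 2")
    rng = np.random.default_rng(seed)
    n_branches = n_genes // 2
    caps = np.round(rng.uniform(2.0, 6.0, size=n_branches), 3)
    doc = ModelDocument(name=f"multigene{n_genes}")
    _species(doc, "hub", "hub metabolite")
    _species(doc, "prod", "product")
    _species(doc, "bio", "biomass")
    _exchange(doc, "EX_hub", "hub", -float(caps.sum()) - 10.0, 0.0, "nutrient exchange")
    for k in range(n_branches):
        _species(doc, f"I{k}")
        doc.reactions.append(
            ReactionRecord(
                id=f"B{k}a",
                name=f"branch {k} step 1",
                stoichiometry={"hub": -1.0, f"I{k}": 1.0},
                lower_bound=0.0,
                upper_bound=float(caps[k]),
                gpr=GeneRef(f"G{k}a"),
            )
        )
        doc.reactions.append(
            ReactionRecord(
                id=f"B{k}b",
                name=f"branch {k} step 2",
                stoichiometry={f"I{k}": -1.0, "prod": 1.0},
                lower_bound=0.0,
                gpr=GeneRef(f"G{k}b"),
            )
        )
    doc.reactions.append(
        ReactionRecord(
            id="growth",
            name="biomass pseudoreaction",
            stoichiometry={"prod": -1.0, "bio": 1.0},
            lower_bound=0.0,
            sbo_term=SBO_OMITTED,
        )
    )
    _exchange(doc, "EX_bio", "bio", 0.0, math.inf, "biomass exchange")
    doc.objective_id = "EX_bio"
    doc.validate()
    return doc


#: named fixtures addressable from the command line
FIXTURES: Dict[str, object] = {
    "chain": make_chain_fixture,
    "two_branch": make_two_branch_fixture,
    "branched": make_branched_fixture,
    "random": make_random_feasible,
    "multigene": make_multigene_fixture,
}
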