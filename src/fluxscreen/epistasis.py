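"""Pairwise genetic interactions by non-scaled multiplicative epistasis.

Fitness W of a perturbed model is its maximum biomass flux relative to the
wild type.  For genes x and y perturbed singly and jointly,

    epsilon = W_xy − W_x · W_y

deviates from 0 exactly when the two genes do not contribute independently
and multiplicatively to fitness: epsilon > 0 is a buffering (positive)
interaction, epsilon < 0 an aggravating (negative) one.

Perturbations here are fractional flux restrictions: every reaction
annotated to a gene is limited to a fraction of its wild-type *geometric*
FBA flux — the centred reference makes the screen deterministic even when
the wild-type optimum is degenerate.  Restricting to 0% recovers hard
deletions; intermediate fractions probe essential reactions too.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fba import CompiledProblem, FluxSolution, SolverError, geometric_fba
from .model import ModelDocument

__all__ = [
    "EpistasisResult",
    "epsilon",
    "fitness",
    "pairwise_screen",
    "restriction_profile",
    "INTERACTION_TOLERANCE",
    "DEFAULT_FRACTIONS",
]

#: |epsilon| above this counts as an interaction
INTERACTION_TOLERANCE = 1e-4

#: restriction grid: 0% to 90% of wild-type flux in 10% steps
DEFAULT_FRACTIONS = tuple(round(0.1 * k, 1) for k in range(10))


def epsilon(w_x: float, w_y: float, w_xy: float) -> float:
    """Non-scaled multiplicative epistasis, W_xy − W_x·W_y."""
    for label, w in (("w_x", w_x), ("w_y", w_y), ("w_xy", w_xy)):
        if not 0 <= w <= 1:
            raise ValueError(f"fitness {label}={w} outside [0, 1]")
    return w_xy - w_x * w_y


@dataclass
class EpistasisResult:
    """A full pairwise screen at one restriction fraction."""

    restriction_fraction: float
    wild_type_objective: float
    interaction_tolerance: float
    #: single-perturbation fitness per gene
    fitness: Dict[str, float] = field(default_factory=dict)
    #: one record per unordered pair: (gene_x, gene_y, w_xy, epsilon)
    pairs: List[Tuple[str, str, float, float]] = field(default_factory=list)

    @property
    def n_interactions(self) -> int:
        return sum(1 for *_, e in self.pairs if abs(e) > self.interaction_tolerance)

    @property
    def n_positive(self) -> int:
        return sum(1 for *_, e in self.pairs if e > self.interaction_tolerance)

    @property
    def n_negative(self) -> int:
        return sum(1 for *_, e in self.pairs if e < -self.interaction_tolerance)

    @property
    def fraction_interacting(self) -> float:
        """Fraction of screened gene pairs that interact."""
        return self.n_interactions / len(self.pairs) if self.pairs else 0.0

    def interacting_genes(self) -> FrozenSet[str]:
        out = set()
        for gx, gy, _, e in self.pairs:
            if abs(e) > self.interaction_tolerance:
                out |= {gx, gy}
        return frozenset(out)

    def count_at_tolerance(self, tolerance: float) -> int:
        """Interaction count under an alternative tolerance, for sensitivity
        reporting."""
        return sum(1 for *_, e in self.pairs if abs(e) > tolerance)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_x": gx,
                "gene_y": gy,
                "W_x": self.fitness[gx],
                "W_y": self.fitness[gy],
                "W_xy": w_xy,
                "epsilon": e,
            }
            for gx, gy, w_xy, e in self.pairs
        ]
        return pd.DataFrame(rows, columns=["gene_x", "gene_y", "W_x", "W_y", "W_xy", "epsilon"])


def fitness(
    prob: CompiledProblem,
    restricted_genes: Iterable[str],
    fraction: float,
    reference: FluxSolution,
    wild_type_objective: float,
    sign_preserving: bool = False,
) -> float:
    """Fitness of the model with each listed gene's reactions restricted to
    ``fraction`` of its reference flux: max biomass / wild-type biomass,
    clamped into [0, 1] at solver tolerance.  Infeasible restricted problems
    score 0 (the perturbed organism cannot even rest)."""
    genes = set(restricted_genes)
    overrides: Dict[str, Tuple[float, float]] = {}
    for r in prob.doc.reactions:
        if not (r.gpr.genes() & genes):
            continue
        v_ref = reference.fluxes.get(r.id, 0.0)
        if sign_preserving:
            lo, hi = (0.0, fraction * v_ref) if v_ref >= 0 else (fraction * v_ref, 0.0)
        else:
            band = fraction * abs(v_ref)
            lo, hi = -band, band
        # a reaction shared by several restricted genes is restricted once:
        # the band depends only on the reaction, so overrides are idempotent
        overrides[r.id] = (max(r.lower_bound, lo), min(r.upper_bound, hi))
    sol = prob.solve(bound_overrides=overrides)
    if sol.status == "infeasible":
        return 0.0
    if sol.status != "optimal":
        raise SolverError(f"restricted LP is {sol.status}")
    return min(1.0, max(0.0, sol.objective_value / wild_type_objective))


def perturbation_fitness(
    doc: ModelDocument,
    perturbation,
    wild_type_objective: float,
    reference: Optional[FluxSolution] = None,
    sign_preserving: bool = False,
) -> float:
    """Fitness of an arbitrary :class:`~fluxscreen.perturb.PerturbationSet`
    (deletions plus restrictions) relative to ``wild_type_objective``."""
    from .fba import solve_fba
    from .perturb import apply_perturbation

    if wild_type_objective <= 0:
        raise ValueError("wild-type objective must be positive")
    perturbed = apply_perturbation(doc, perturbation, reference, sign_preserving)
    sol = solve_fba(perturbed)
    if sol.status == "infeasible":
        return 0.0
    if sol.status != "optimal":
        raise SolverError(f"perturbed LP is {sol.status}")
    return min(1.0, max(0.0, sol.objective_value / wild_type_objective))


def pairwise_screen(
    doc: ModelDocument,
    fraction: float = 0.5,
    tolerance: float = INTERACTION_TOLERANCE,
    genes: Optional[Sequence[str]] = None,
    reference: Optional[FluxSolution] = None,
    sign_preserving: bool = False,
    checkpoint_path: Optional[str] = None,
) -> EpistasisResult:
    """Epistasis over every unordered pair of model genes at one restriction
    fraction.

    The wild-type geometric FBA reference is computed once (or supplied);
    single fitnesses W_x once per gene; joint fitnesses once per pair, with
    a reaction annotated to both genes restricted once.  Gene order is
    deterministic (sorted), so a checkpoint file — one completed pair per
    line — makes long screens resumable: pass the same ``checkpoint_path``
    again and finished pairs are loaded instead of recomputed.
    """
    prob = CompiledProblem(doc)
    wt = prob.solve()
    if wt.status != "optimal" or wt.objective_value <= 0:
        raise ValueError(f"wild type not solvable: {wt.status}")
    if reference is None:
        reference = geometric_fba(doc)
    gene_list = sorted(genes) if genes is not None else sorted(doc.genes)

    result = EpistasisResult(
        restriction_fraction=fraction,
        wild_type_objective=wt.objective_value,
        interaction_tolerance=tolerance,
    )
    for g in gene_list:
        result.fitness[g] = fitness(
            prob, [g], fraction, reference, wt.objective_value, sign_preserving
        )

    done: Dict[Tuple[str, str], float] = {}
    if checkpoint_path and os.path.exists(checkpoint_path):
        with open(checkpoint_path) as fh:
            for line in fh:
                gx, gy, w = line.rstrip("\n").split("\t")
                done[(gx, gy)] = float(w)
    ck = open(checkpoint_path, "a") if checkpoint_path else None
    try:
        for i, gx in enumerate(gene_list):
            for gy in gene_list[i + 1 :]:
                key = (gx, gy)
                if key in done:
                    w_xy = done[key]
                else:
                    w_xy = fitness(
                        prob, [gx, gy], fraction, reference,
                        wt.objective_value, sign_preserving,
                    )
                    if ck:
                        ck.write(f"{gx}\t{gy}\t{w_xy!r}\n")
                        ck.flush()
                e = epsilon(result.fitness[gx], result.fitness[gy], w_xy)
                result.pairs.append((gx, gy, w_xy, e))
    finally:
        if ck:
            ck.close()
    return result


def restriction_profile(
    doc: ModelDocument,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    tolerance: float = INTERACTION_TOLERANCE,
    genes: Optional[Sequence[str]] = None,
    sign_preserving: bool = False,
) -> Tuple[List[EpistasisResult], pd.DataFrame]:
    """One full pairwise screen per restriction level, sharing a single
    geometric-FBA reference; returns the per-level results and a summary
    table (total / positive / negative interaction counts per level)."""
    reference = geometric_fba(doc)
    results = [
        pairwise_screen(
            doc, f, tolerance, genes=genes, reference=reference,
            sign_preserving=sign_preserving,
        )
        for f in fractions
    ]
    summary = pd.DataFrame(
        {
            "fraction": [r.restriction_fraction for r in results],
            "n_pairs": [len(r.pairs) for r in results],
            "n_interactions": [r.n_interactions for r in results],
            "n_positive": [r.n_positive for r in results],
            "n_negative": [r.n_negative for r in results],
            "fraction_interacting": [r.fraction_interacting for r in results],
        }
    )
    return results, summary
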