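"""Essentiality and auxotrophy evaluation of a metabolic model.

A single-gene deletion screen runs one FBA per gene and calls each deletion
viable or inviable against a threshold fraction of the wild-type objective.
Calls are scored against curated gene lists with "positive" meaning
*predicted growth*: a true positive is a gene off the essential/auxotrophic
lists whose deletion still grows in silico, a true negative a listed gene
whose deletion does not.  The auxotrophy screen classifies each candidate
gene by growth in a minimal versus a fully supplemented medium.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .fba import CompiledProblem, SolverError
from .model import ModelDocument
from .perturb import MediumSpec, apply_medium, supplemented_medium

__all__ = [
    "GeneLists",
    "ConfusionMatrix",
    "AuxotrophyCall",
    "ScreenResult",
    "single_deletion_screen",
    "score_essentiality",
    "auxotrophy_screen",
    "compare_models",
    "read_gene_list",
    "VIABILITY_THRESHOLD",
]

#: viable iff objective > threshold × wild-type objective
VIABILITY_THRESHOLD = 1e-6


@dataclass
class GeneLists:
    """Curated phenotype lists: genes essential for viability and genes whose
    deletion induces an auxotrophy (rescuable by supplementation)."""

    essential: Set[str] = field(default_factory=set)
    auxotroph_inducing: Set[str] = field(default_factory=set)

    @property
    def condition_negative(self) -> Set[str]:
        """Genes expected NOT to grow when deleted (either list)."""
        return self.essential | self.auxotroph_inducing


def read_gene_list(path: str) -> Set[str]:
    """One ORF name per line; ``#`` starts a comment; blank lines ignored."""
    out: Set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out


@dataclass
class ConfusionMatrix:
    """Viability-prediction counts.  Positive = predicted growth."""

    tp: int = 0  # predicted growth, gene not listed
    fn: int = 0  # predicted no growth, gene not listed
    fp: int = 0  # predicted growth, gene listed essential/auxotrophic
    tn: int = 0  # predicted no growth, gene listed

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else math.nan

    @property
    def combined_accuracy(self) -> float:
        """Product of sensitivity and specificity.

        Reported in the model-comparison literature under the name
        "geometric mean overall predictive accuracy", but the printed values
        there are the plain product, without the square root; this field
        keeps the computable definition.
        """
        return self.sensitivity * self.specificity


@dataclass
class ScreenResult:
    """Outcome of a single-deletion screen."""

    wild_type_objective: float
    #: gene -> (objective after deletion, viable flag)
    results: Dict[str, Tuple[float, bool]] = field(default_factory=dict)
    threshold: float = VIABILITY_THRESHOLD

    @property
    def viable_genes(self) -> Set[str]:
        return {g for g, (_, ok) in self.results.items() if ok}

    @property
    def inviable_genes(self) -> Set[str]:
        return {g for g, (_, ok) in self.results.items() if not ok}


def _deletion_objective(prob: CompiledProblem, genes: Set[str]) -> float:
    """Objective after knocking out ``genes``, via bound overrides on the
    compiled problem (equivalent to apply_deletions + solve_fba)."""
    overrides = {
        r.id: (0.0, 0.0)
        for r in prob.doc.reactions
        if not r.gpr.evaluate(genes)
    }
    sol = prob.solve(bound_overrides=overrides)
    if sol.status == "optimal":
        return sol.objective_value
    if sol.status == "infeasible":
        return 0.0
    raise SolverError(f"deletion LP is {sol.status}")


def single_deletion_screen(
    doc: ModelDocument,
    medium: Optional[MediumSpec] = None,
    genes: Optional[Iterable[str]] = None,
    threshold: float = VIABILITY_THRESHOLD,
) -> ScreenResult:
    """One FBA per gene with that gene deleted.

    The wild type is solved once; a deletion is viable iff its objective
    exceeds ``threshold`` × wild type.  A wild type that cannot grow in the
    given medium makes every call meaningless, so that is an error.
    """
    work = apply_medium(doc, medium) if medium is not None else doc
    prob = CompiledProblem(work)
    wt = prob.solve()
    if wt.status != "optimal" or wt.objective_value <= 0:
        raise ValueError(
            f"wild type does not grow in medium "
            f"{medium.name if medium else '(as distributed)'}: "
            f"status {wt.status}, objective {wt.objective_value}"
        )
    cut = threshold * wt.objective_value
    gene_set = sorted(genes) if genes is not None else sorted(work.genes)
    out = ScreenResult(wild_type_objective=wt.objective_value, threshold=threshold)
    for gene in gene_set:
        obj = _deletion_objective(prob, {gene})
        out.results[gene] = (obj, obj > cut)
    return out


def score_essentiality(screen: ScreenResult, lists: GeneLists) -> ConfusionMatrix:
    """Score screen calls against the gene lists (positive = predicted
    growth; condition-negative = listed essential or auxotroph-inducing)."""
    unmatched = lists.condition_negative - set(screen.results)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} listed genes absent from the screen "
            f"(not in model): {sorted(unmatched)[:5]}..."
        )
    cm = ConfusionMatrix()
    negative = lists.condition_negative
    for gene, (_, viable) in screen.results.items():
        if gene in negative:
            if viable:
                cm.fp += 1
            else:
                cm.tn += 1
        else:
            if viable:
                cm.tp += 1
            else:
                cm.fn += 1
    return cm


@dataclass
class AuxotrophyCall:
    """Three-way classification of a candidate auxotrophy gene."""

    gene: str
    objective_minimal: float
    objective_supplemented: float
    category: str  # auxotroph_confirmed | viable_in_minimal | inviable_in_supplemented

    CATEGORIES = ("auxotroph_confirmed", "viable_in_minimal", "inviable_in_supplemented")


def auxotrophy_screen(
    doc: ModelDocument,
    genes: Iterable[str],
    minimal: Optional[MediumSpec] = None,
    supplemented: Optional[MediumSpec] = None,
    threshold: float = VIABILITY_THRESHOLD,
) -> List[AuxotrophyCall]:
    """Classify candidate genes by deletion growth in minimal vs supplemented
    media.

    * no growth minimal, growth supplemented → ``auxotroph_confirmed``
      (the expected behaviour of an auxotroph mutant);
    * growth in minimal → ``viable_in_minimal`` (auxotrophy missed);
    * no growth in either → ``inviable_in_supplemented`` (supplementation
      cannot rescue the deletion in silico).

    Both media must support wild-type growth.
    """
    genes = sorted(set(genes))
    media: List[Tuple[str, CompiledProblem, float]] = []
    for tag, medium in (("minimal", minimal), ("supplemented", supplemented)):
        work = apply_medium(doc, medium) if medium is not None else (
            doc if tag == "minimal" else apply_medium(doc, supplemented_medium(doc))
        )
        prob = CompiledProblem(work)
        wt = prob.solve()
        if wt.status != "optimal" or wt.objective_value <= 0:
            raise ValueError(f"wild type does not grow in the {tag} medium")
        media.append((tag, prob, threshold * wt.objective_value))

    calls: List[AuxotrophyCall] = []
    (_, prob_min, cut_min), (_, prob_sup, cut_sup) = media
    for gene in genes:
        o_min = _deletion_objective(prob_min, {gene})
        o_sup = _deletion_objective(prob_sup, {gene})
        if o_min > cut_min:
            cat = "viable_in_minimal"
        elif o_sup > cut_sup:
            cat = "auxotroph_confirmed"
        else:
            cat = "inviable_in_supplemented"
        calls.append(AuxotrophyCall(gene, o_min, o_sup, cat))
    return calls


def compare_models(
    entries: Sequence[Tuple[ModelDocument, GeneLists]],
    minimal: Optional[Sequence[Optional[MediumSpec]]] = None,
    blocked: bool = True,
) -> pd.DataFrame:
    """One row of census and predictive metrics per (model, gene-lists) pair.

    Census columns: metabolite/reaction/gene/exchange counts and blocked
    fraction; viability columns from the confusion matrix; auxotrophy columns
    from the three-way screen.  A model whose screen fails contributes its
    census columns and NaN metrics, with the error recorded in the ``error``
    column, so one broken model never hides the rest.
    """
    from .reconstruction import blocked_reactions  # local import: cycle

    rows = []
    for i, (doc, lists) in enumerate(entries):
        medium = minimal[i] if minimal is not None else None
        internal = [s for s in doc.species if not s.is_boundary]
        row: Dict[str, object] = {
            "model": doc.name or f"model_{i}",
            "n_metabolites": len(internal),
            "n_reactions": len(doc.reactions),
            "n_genes": len(doc.genes),
            "n_exchange": len(doc.exchange_reactions()),
            "n_isa": sum(r.is_isa for r in doc.reactions),
            "error": "",
        }
        try:
            if blocked:
                _, frac = blocked_reactions(doc)
                row["blocked_fraction"] = frac
            screen = single_deletion_screen(doc, medium)
            cm = score_essentiality(screen, lists)
            row.update(
                tp=cm.tp, fn=cm.fn, fp=cm.fp, tn=cm.tn,
                sensitivity=cm.sensitivity, specificity=cm.specificity,
                ppv=cm.ppv, npv=cm.npv, combined_accuracy=cm.combined_accuracy,
            )
            in_model = sorted(lists.auxotroph_inducing & doc.genes)
            if in_model:
                calls = auxotrophy_screen(doc, in_model, minimal=medium)
                for cat in AuxotrophyCall.CATEGORIES:
                    row[cat] = sum(1 for c in calls if c.category == cat)
        except (ValueError, SolverError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
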