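"""Linear-programming core: FBA, flux variability, geometric FBA.

All three operate on the steady-state flux polytope

    P = { v : S v = 0,  lb <= v <= ub }

built from a :class:`~fluxscreen.model.ModelDocument`.  FBA maximises (or
minimises) the flux of one objective reaction over P; flux variability
analysis (FVA) delimits each reaction's flux range at a fixed objective
level; geometric FBA selects the unique central point of the optimal face,
making downstream analyses (flux reports, reference fluxes for restriction
screens) independent of solver tie-breaking.

The solver backend is HiGHS via :func:`scipy.optimize.linprog`.  Infinite
bounds are replaced by a large finite magnitude only at hand-off (the COBRA
convention of 1000 flux units by default); documents keep true infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import ModelDocument, stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "VariabilityRange",
    "CompiledProblem",
    "SolverError",
    "solve_fba",
    "flux_variability",
    "geometric_fba",
    "DEFAULT_BIG_BOUND",
    "CONTRACT_TOL",
]

#: finite stand-in for an infinite bound at solver hand-off
DEFAULT_BIG_BOUND = 1000.0
#: tolerance for contract checks (objective agreement, convergence)
CONTRACT_TOL = 1e-6


class SolverError(RuntimeError):
    """The LP backend failed in a way that is not a plain infeasibility."""


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class VariabilityRange:
    """Per-reaction (min, max) flux at a fixed objective level."""

    ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __getitem__(self, rid: str) -> Tuple[float, float]:
        return self.ranges[rid]

    def width(self, rid: str) -> float:
        lo, hi = self.ranges[rid]
        return hi - lo


_STATUS = {0: "optimal", 1: "iteration-limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


class CompiledProblem:
    """A document compiled once into solver arrays, with cheap bound overrides.

    Screens (single deletions, pairwise restrictions) solve thousands of LPs
    that differ from the wild type only in a few bounds; recompiling S every
    time would dominate the runtime.
    """

    def __init__(self, doc: ModelDocument, big: float = DEFAULT_BIG_BOUND):
        doc.validate()
        self.doc = doc
        self.big = big
        S, species_ids, reaction_ids = stoichiometric_matrix(doc)
        self.S = S
        self.species_ids = species_ids
        self.reaction_ids = reaction_ids
        self.index = {rid: j for j, rid in enumerate(reaction_ids)}
        self.lb = np.array(
            [max(r.lower_bound, -big) for r in doc.reactions], dtype=float
        )
        self.ub = np.array([min(r.upper_bound, big) for r in doc.reactions], dtype=float)

    def objective_vector(self, objective_id: str) -> np.ndarray:
        c = np.zeros(len(self.reaction_ids))
        c[self.index[objective_id]] = 1.0
        return c

    def solve(
        self,
        objective_id: Optional[str] = None,
        maximize: bool = True,
        bound_overrides: Optional[Dict[str, Tuple[float, float]]] = None,
        extra_A_ub: Optional[np.ndarray] = None,
        extra_b_ub: Optional[np.ndarray] = None,
        c: Optional[np.ndarray] = None,
    ) -> FluxSolution:
        """Solve max/min c·v over P, optionally with per-reaction bound
        overrides and extra inequality rows A_ub v <= b_ub."""
        if c is None:
            c = self.objective_vector(objective_id or self.doc.objective_id)
        lb, ub = self.lb, self.ub
        if bound_overrides:
            lb, ub = lb.copy(), ub.copy()
            for rid, (lo, hi) in bound_overrides.items():
                j = self.index[rid]
                lb[j] = max(lo, -self.big)
                ub[j] = min(hi, self.big)
        res = linprog(
            -c if maximize else c,
            A_ub=extra_A_ub,
            b_ub=extra_b_ub,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        status = _STATUS.get(res.status, "numerical")
        if status in ("iteration-limit", "numerical"):
            raise SolverError(f"LP backend failure: {res.message}")
        if status != "optimal":
            return FluxSolution(status=status, objective_value=math.nan)
        obj = float(c @ res.x)
        return FluxSolution(
            status="optimal",
            objective_value=obj,
            fluxes={rid: float(res.x[j]) for rid, j in self.index.items()},
        )


def solve_fba(
    doc: ModelDocument,
    objective_id: Optional[str] = None,
    maximize: bool = True,
    big: float = DEFAULT_BIG_BOUND,
) -> FluxSolution:
    """Flux balance analysis: optimise one reaction's flux over the
    steady-state polytope.

    A model that cannot grow but can rest (v = 0 feasible) reports status
    ``optimal`` with objective 0, so screens can compare against a viability
    threshold; ``infeasible`` is reserved for genuinely empty polytopes.
    """
    return CompiledProblem(doc, big=big).solve(objective_id, maximize=maximize)


def flux_variability(
    doc: ModelDocument,
    reaction_ids: Optional[Sequence[str]] = None,
    objective_fraction: float = 1.0,
    objective_id: Optional[str] = None,
    big: float = DEFAULT_BIG_BOUND,
) -> VariabilityRange:
    """Min and max flux per reaction subject to c·v >= fraction × optimum.

    ``objective_fraction=0`` frees the objective entirely, the regime used
    for blocked-reaction detection; ``1.0`` delimits the optimal face.
    """
    prob = CompiledProblem(doc, big=big)
    return _fva(prob, reaction_ids, objective_fraction, objective_id)


def _fva(
    prob: CompiledProblem,
    reaction_ids: Optional[Sequence[str]],
    objective_fraction: float,
    objective_id: Optional[str] = None,
) -> VariabilityRange:
    objective_id = objective_id or prob.doc.objective_id
    rids = list(reaction_ids) if reaction_ids is not None else list(prob.reaction_ids)
    A_ub = b_ub = None
    if objective_fraction > 0:
        base = prob.solve(objective_id)
        if base.status != "optimal":
            raise SolverError(
                f"base FBA problem is {base.status}; variability undefined"
            )
        c = prob.objective_vector(objective_id)
        A_ub = -c[None, :]
        b_ub = np.array([-objective_fraction * base.objective_value])
    out: Dict[str, Tuple[float, float]] = {}
    for rid in rids:
        c_r = prob.objective_vector(rid)
        lo = prob.solve(c=c_r, maximize=False, extra_A_ub=A_ub, extra_b_ub=b_ub)
        hi = prob.solve(c=c_r, maximize=True, extra_A_ub=A_ub, extra_b_ub=b_ub)
        if lo.status != "optimal" or hi.status != "optimal":
            raise SolverError(f"variability subproblem for {rid} is {lo.status}/{hi.status}")
        out[rid] = (lo.objective_value, hi.objective_value)
    return VariabilityRange(ranges=out)


def geometric_fba(
    doc: ModelDocument,
    objective_id: Optional[str] = None,
    big: float = DEFAULT_BIG_BOUND,
    tol: float = CONTRACT_TOL,
    max_iter: int = 50,
) -> FluxSolution:
    """A unique, centered optimal flux distribution.

    Degenerate FBA problems have a whole face of optimal flux vectors; the
    solver's pick among them is arbitrary.  This routine fixes the objective
    at its optimum, then iterates: delimit each reaction's range by FVA,
    minimise the summed absolute (L1) deviation from the range midpoints,
    constrain the total deviation to that minimum, and re-delimit.  The
    bounding box of the remaining optima contracts monotonically; iteration
    stops when its widest side falls below ``tol`` (or after ``max_iter``
    rounds).  The result is invariant under reaction reordering and solver
    restarts up to ``tol``.
    """
    prob = CompiledProblem(doc, big=big)
    objective_id = objective_id or doc.objective_id
    base = prob.solve(objective_id)
    if base.status != "optimal":
        raise SolverError(f"FBA problem is {base.status}; geometric FBA undefined")
    n = len(prob.reaction_ids)
    c_obj = prob.objective_vector(objective_id)
    opt = base.objective_value

    # working polytope: S v = 0, bounds, c·v = opt (as paired inequalities)
    # variables are [v, d] with d_i >= |v_i - m_i|
    S = prob.S
    m_rows = S.shape[0]
    A_eq = np.hstack([S, np.zeros((m_rows, n))])
    b_eq = np.zeros(m_rows)

    lb_v, ub_v = prob.lb.copy(), prob.ub.copy()
    fix_lo = np.hstack([-c_obj, np.zeros(n)])  # -c·v <= -opt
    fix_hi = np.hstack([c_obj, np.zeros(n)])  # c·v <= opt

    def fva_within(extra_rows: list, extra_rhs: list) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.empty(n)
        hi = np.empty(n)
        bounds = np.column_stack(
            [np.hstack([lb_v, np.zeros(n)]), np.hstack([ub_v, np.full(n, np.inf)])]
        )
        A = np.vstack([fix_lo, fix_hi] + extra_rows)
        b = np.concatenate(
            [np.array([-opt, opt])] + [np.atleast_1d(x) for x in extra_rhs]
        )
        for j in range(n):
            c = np.zeros(2 * n)
            c[j] = 1.0
            for sense, store in ((1.0, lo), (-1.0, hi)):
                res = linprog(
                    sense * c, A_ub=A, b_ub=b, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                    method="highs",
                )
                if res.status != 0:
                    raise SolverError(
                        f"geometric FBA variability subproblem failed: {res.message}"
                    )
                store[j] = sense * res.fun
        return lo, hi

    lo, hi = fva_within([], [])
    for _ in range(max_iter):
        if np.max(hi - lo) < tol:
            break
        m = 0.5 * (lo + hi)
        # d_i >= |v_i - m_i| as two inequality blocks
        dev_pos = np.hstack([np.eye(n), -np.eye(n)])  # v - d <= m
        dev_neg = np.hstack([-np.eye(n), -np.eye(n)])  # -v - d <= -m
        A = np.vstack([fix_lo, fix_hi, dev_pos, dev_neg])
        b = np.hstack([[-opt, opt], m, -m])
        bounds = np.column_stack(
            [np.hstack([lb_v, np.zeros(n)]), np.hstack([ub_v, np.full(n, np.inf)])]
        )
        c = np.hstack([np.zeros(n), np.ones(n)])
        res = linprog(c, A_ub=A, b_ub=b, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
        if res.status != 0:
            raise SolverError(f"geometric FBA centering LP failed: {res.message}")
        total = float(res.fun)
        # restrict to the centering LP's optimal set and re-delimit
        lo, hi = fva_within(
            [dev_pos, dev_neg, c[None, :]], [m, -m, np.array([total + tol * 0.1])]
        )
        lb_v = np.maximum(lb_v, lo - tol)
        ub_v = np.minimum(ub_v, hi + tol)

    # the residual box is narrower than tol; its midpoint is the
    # permutation-invariant answer (within tol of a feasible optimum)
    mid = 0.5 * (lo + hi)
    fluxes = {rid: float(mid[prob.index[rid]]) for rid in prob.reaction_ids}
    return FluxSolution(
        status="optimal", objective_value=float(c_obj @ mid), fluxes=fluxes
    )
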