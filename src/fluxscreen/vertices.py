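"""Exact FBA optimum by brute-force vertex enumeration.

For tiny networks the steady-state polytope { v : S v = 0, lb <= v <= ub }
has few vertices, and a linear objective attains its optimum at one of them.
Enumerating every vertex gives an exact optimum by a route entirely
independent of the LP solver, which makes it the validation oracle for
:func:`fluxscreen.fba.solve_fba` on generated fixtures.

At a vertex, at least n - rank(S) variables sit on a bound.  We enumerate
every choice of rank(S) "free" columns, every lower/upper assignment of the
fixed ones, solve the resulting square system, and keep solutions that land
inside the bounds.  Cost grows as C(n, r)·2^(n-r); keep n at or below ~12.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Tuple

import numpy as np

from .fba import DEFAULT_BIG_BOUND
from .model import ModelDocument, stoichiometric_matrix

__all__ = ["enumerate_optimum"]


def enumerate_optimum(
    doc: ModelDocument,
    objective_id: Optional[str] = None,
    maximize: bool = True,
    big: float = DEFAULT_BIG_BOUND,
    tol: float = 1e-7,
    max_reactions: int = 14,
) -> Tuple[float, np.ndarray]:
    """Return ``(objective, flux_vector)`` at the best enumerated vertex.

    Raises ``ValueError`` for networks above ``max_reactions`` columns (the
    enumeration is exponential) and ``RuntimeError`` when no vertex is
    feasible (an empty polytope — note v = 0 is a vertex candidate whenever
    the bounds admit it).
    """
    rids = [r.id for r in doc.reactions]
    n = len(rids)
    if n > max_reactions:
        raise ValueError(f"vertex enumeration limited to {max_reactions} reactions, got {n}")
    S, _, _ = stoichiometric_matrix(doc)
    lb = np.array([max(r.lower_bound, -big) for r in doc.reactions])
    ub = np.array([min(r.upper_bound, big) for r in doc.reactions])
    c = np.zeros(n)
    c[rids.index(objective_id or doc.objective_id)] = 1.0
    sign = 1.0 if maximize else -1.0

    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    best: Optional[Tuple[float, np.ndarray]] = None

    for free in itertools.combinations(range(n), r):
        free = list(free)
        fixed = [j for j in range(n) if j not in free]
        S_free = S[:, free]
        if np.linalg.matrix_rank(S_free) < r:
            continue
        S_fixed = S[:, fixed]
        for picks in itertools.product((0, 1), repeat=len(fixed)):
            v = np.empty(n)
            v_fixed = np.array(
                [lb[j] if p == 0 else ub[j] for j, p in zip(fixed, picks)]
            )
            rhs = -S_fixed @ v_fixed if fixed else np.zeros(S.shape[0])
            sol, residual, _, _ = np.linalg.lstsq(S_free, rhs, rcond=None)
            if np.linalg.norm(S_free @ sol - rhs) > tol * (1 + np.linalg.norm(rhs)):
                continue
            v[free] = sol
            v[fixed] = v_fixed
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            obj = float(c @ v)
            if best is None or sign * obj > sign * best[0] + 0:
                best = (obj, v.copy())
    if best is None:
        raise RuntimeError("no feasible vertex found: empty steady-state polytope")
    return best
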