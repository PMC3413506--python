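"""FBA, flux variability, and geometric FBA against independent oracles."""

import math
import random

import numpy as np
import pytest

from fluxscreen import fixtures as fx
from fluxscreen.fba import (
    SolverError,
    flux_variability,
    geometric_fba,
    solve_fba,
)
from fluxscreen.gpr import GeneRef
from fluxscreen.model import ModelDocument, ReactionRecord, SpeciesRecord
from fluxscreen.vertices import enumerate_optimum


def parallel_pathways_doc(demand=10.0):
    """Uptake feeding two identical unit branches into a fixed demand."""
    doc = ModelDocument(name="parallel")
    for sid in ("A", "B"):
        doc.species.append(SpeciesRecord(id=sid, compartment="cell"))
    doc.species.append(SpeciesRecord(id="A_b", compartment="env", is_boundary=True))
    doc.species.append(SpeciesRecord(id="B_b", compartment="env", is_boundary=True))
    doc.reactions = [
        ReactionRecord(id="EX_A", stoichiometry={"A": -1, "A_b": 1},
                       lower_bound=-demand, upper_bound=0),
        ReactionRecord(id="P1", stoichiometry={"A": -1, "B": 1}, lower_bound=0),
        ReactionRecord(id="P2", stoichiometry={"A": -1, "B": 1}, lower_bound=0),
        ReactionRecord(id="EX_B", stoichiometry={"B": -1, "B_b": 1},
                       lower_bound=0, upper_bound=math.inf),
    ]
    doc.objective_id = "EX_B"
    return doc


class TestSolveFba:
    def test_bound_limited_chain(self, chain):
        sol = solve_fba(chain)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0)
        # the whole chain carries the uptake flux
        for rid in ("R1", "R2", "growth", "EX_bio"):
            assert sol.fluxes[rid] == pytest.approx(10.0)
        assert sol.fluxes["EX_M1"] == pytest.approx(-10.0)

    def test_missing_cofactor_gives_zero_growth_not_infeasible(self, branched):
        # block cofactor regeneration: the required cofactor is never recharged
        branched.reaction("COFREG").upper_bound = 0.0
        sol = solve_fba(branched)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_matches_vertex_enumeration_on_random_networks(self, seed):
        doc = fx.make_random_feasible(seed)
        sol = solve_fba(doc)
        obj, _ = enumerate_optimum(doc)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(obj, rel=1e-6, abs=1e-6)

    def test_steady_state_and_bounds_hold_at_optimum(self, branched):
        from fluxscreen.model import stoichiometric_matrix

        sol = solve_fba(branched)
        S, _, rids = stoichiometric_matrix(branched)
        v = np.array([sol.fluxes[r] for r in rids])
        assert np.max(np.abs(S @ v)) < 1e-6
        for r in branched.reactions:
            assert sol.fluxes[r.id] >= max(r.lower_bound, -1000.0) - 1e-6
            assert sol.fluxes[r.id] <= min(r.upper_bound, 1000.0) + 1e-6

    def test_tightening_a_bound_never_raises_the_optimum(self, chain):
        base = solve_fba(chain).objective_value
        for rid in ("R1", "R2", "EX_M1"):
            tight = chain.copy()
            r = tight.reaction(rid)
            if r.lower_bound < 0:
                r.lower_bound = r.lower_bound / 2
            else:
                r.upper_bound = 4.0
            assert solve_fba(tight).objective_value <= base + 1e-9


class TestFluxVariability:
    def test_two_identical_branches_each_range_zero_to_demand(self):
        doc = parallel_pathways_doc(10.0)
        var = flux_variability(doc, ["P1", "P2"], objective_fraction=1.0)
        for rid in ("P1", "P2"):
            lo, hi = var[rid]
            assert lo == pytest.approx(0.0, abs=1e-7)
            assert hi == pytest.approx(10.0, abs=1e-7)

    def test_obligatory_reaction_range_collapses(self, chain):
        var = flux_variability(chain, ["R1"], objective_fraction=1.0)
        lo, hi = var["R1"]
        assert lo == pytest.approx(10.0) and hi == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", [2, 5, 11])
    def test_ranges_contain_every_enumerated_vertex(self, seed):
        # oracle: each vertex flux must lie inside the FVA range at fraction 0
        doc = fx.make_random_feasible(seed)
        var = flux_variability(doc, objective_fraction=0.0)
        _, v = enumerate_optimum(doc)
        rids = [r.id for r in doc.reactions]
        for j, rid in enumerate(rids):
            lo, hi = var[rid]
            assert lo - 1e-6 <= v[j] <= hi + 1e-6
            assert lo <= hi + 1e-9


class TestGeometricFba:
    def test_unique_optimum_equals_plain_fba(self, chain):
        plain = solve_fba(chain)
        geo = geometric_fba(chain)
        assert geo.objective_value == pytest.approx(plain.objective_value, rel=1e-6)
        for rid, v in plain.fluxes.items():
            assert geo.fluxes[rid] == pytest.approx(v, abs=1e-5)

    def test_symmetric_branches_split_evenly(self):
        doc = parallel_pathways_doc(10.0)
        geo = geometric_fba(doc)
        assert geo.fluxes["P1"] == pytest.approx(5.0, abs=1e-5)
        assert geo.fluxes["P2"] == pytest.approx(5.0, abs=1e-5)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_invariant_under_reaction_permutation(self, seed, two_branch):
        base = geometric_fba(two_branch)
        shuffled = two_branch.copy()
        random.Random(seed).shuffle(shuffled.reactions)
        geo = geometric_fba(shuffled)
        for rid in base.fluxes:
            assert geo.fluxes[rid] == pytest.approx(base.fluxes[rid], abs=1e-5)

    def test_attains_the_fba_optimum(self, two_branch):
        assert geometric_fba(two_branch).objective_value == pytest.approx(
            solve_fba(two_branch).objective_value, rel=1e-6
        )


def test_infeasible_base_problem_reported():
    doc = ModelDocument(
        species=[SpeciesRecord(id="A", compartment="cell")],
        reactions=[
            ReactionRecord(id="in", stoichiometry={"A": 1}, lower_bound=1, upper_bound=2),
        ],
        objective_id="in",
    )
    # forced production with no consumer: S v = 0 is unsatisfiable
    sol = solve_fba(doc)
    assert sol.status == "infeasible"
    with pytest.raises(SolverError):
        flux_variability(doc, ["in"], objective_fraction=1.0)
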