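"""Media, deletions, anaerobic shift, and fractional flux restriction."""

import math

import pytest

from fluxscreen import fixtures as fx
from fluxscreen.fba import flux_variability, geometric_fba, solve_fba
from fluxscreen.perturb import (
    AnaerobicSpec,
    MediumSpec,
    anaerobic_transform,
    apply_deletions,
    apply_medium,
    restrict_gene_flux,
    supplemented_medium,
)


class TestDeletions:
    def test_deleting_unannotated_gene_changes_nothing(self, chain):
        base = solve_fba(chain).objective_value
        with pytest.warns(UserWarning, match="not in model"):
            out = apply_deletions(chain, {"NOT_A_GENE"})
        assert solve_fba(out).objective_value == pytest.approx(base)

    def test_deleting_sole_pathway_gene_kills_growth(self, chain):
        out = apply_deletions(chain, {"G1"})
        assert solve_fba(out).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_isoenzymes_survive_single_deletions(self, branched):
        for gene in ("GOR1", "GOR2"):
            out = apply_deletions(branched, {gene})
            assert solve_fba(out).objective_value == pytest.approx(2.5)
        both = apply_deletions(branched, {"GOR1", "GOR2"})
        assert solve_fba(both).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_complex_dies_with_either_subunit(self, branched):
        for gene in ("GC1", "GC2"):
            out = apply_deletions(branched, {gene})
            assert solve_fba(out).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_sequential_deletions_equal_joint_deletion(self, branched):
        seq = apply_deletions(apply_deletions(branched, {"GOR1"}), {"GL1"})
        joint = apply_deletions(branched, {"GOR1", "GL1"})
        assert solve_fba(seq).objective_value == pytest.approx(
            solve_fba(joint).objective_value
        )

    def test_input_document_is_untouched(self, branched):
        before = [(r.lower_bound, r.upper_bound) for r in branched.reactions]
        apply_deletions(branched, {"GB"})
        assert [(r.lower_bound, r.upper_bound) for r in branched.reactions] == before

    def test_agreement_with_cobra_deletion_screen(self, branched, cobra_model):
        from cobra.flux_analysis import single_gene_deletion

        model = cobra_model(branched)
        model.objective = "EX_bio"
        table = single_gene_deletion(model)
        for ids, growth in zip(table["ids"], table["growth"]):
            gene = next(iter(ids))
            ours = solve_fba(apply_deletions(branched, {gene})).objective_value
            assert ours == pytest.approx(growth, abs=1e-6), gene


class TestMedium:
    def test_closing_all_uptake_stops_growth(self, branched):
        closed = MediumSpec(bounds={}, name="nothing")
        out = apply_medium(branched, closed)
        assert solve_fba(out).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_application_is_idempotent(self, branched):
        med = MediumSpec(
            bounds={"EX_glc": (-5.0, 0.0), "EX_o2": (-1000.0, 0.0)}, name="lean"
        )
        once = apply_medium(branched, med)
        twice = apply_medium(once, med)
        assert [(r.lower_bound, r.upper_bound) for r in once.reactions] == [
            (r.lower_bound, r.upper_bound) for r in twice.reactions
        ]
        assert solve_fba(once).objective_value == pytest.approx(1.25)

    def test_supplementation_rescues_blocked_synthesis(self, branched):
        # deleting alanine synthesis starves biomass in minimal medium;
        # opening the alanine exchange is the unique rescue
        mutant = apply_deletions(branched, {"GAux"})
        assert solve_fba(mutant).objective_value == pytest.approx(0.0, abs=1e-9)
        rescued = apply_medium(mutant, supplemented_medium(mutant))
        assert solve_fba(rescued).objective_value > 1.0

    def test_non_exchange_id_rejected(self, branched):
        with pytest.raises(ValueError, match="not an exchange"):
            apply_medium(branched, MediumSpec(bounds={"GROWTH": (0, 1)}))
        with pytest.raises(KeyError):
            apply_medium(branched, MediumSpec(bounds={"EX_nope": (0, 1)}))


class TestAnaerobic:
    def test_closing_oxygen_alone_stops_growth(self, branched):
        branched.reaction("EX_o2").lower_bound = 0.0
        assert solve_fba(branched).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_full_transform_restores_growth(self, branched):
        out = anaerobic_transform(branched)
        assert solve_fba(out).objective_value == pytest.approx(10.0 / 3.0)

    def test_aerobic_lipid_pseudoreaction_is_silenced(self, branched):
        out = anaerobic_transform(branched)
        var = flux_variability(out, ["LIPA", "LIPN"], objective_fraction=1.0)
        assert var["LIPA"] == pytest.approx((0.0, 0.0), abs=1e-9)
        lo, hi = var["LIPN"]
        assert lo > 0  # all anaerobic optima route lipid through the variant

    def test_explicit_spec_overrides_name_matching(self, branched):
        spec = AnaerobicSpec(
            oxygen_exchange="EX_o2",
            supplement_exchanges=("EX_ergo",),
            aerobic_lipid="LIPA",
            anaerobic_lipid="LIPN",
        )
        out = anaerobic_transform(branched, spec)
        assert solve_fba(out).objective_value == pytest.approx(10.0 / 3.0)

    def test_missing_components_reported_together(self, chain):
        with pytest.raises(KeyError, match="oxygen"):
            anaerobic_transform(chain)


class TestRestriction:
    def test_fraction_zero_equals_deletion(self, chain):
        ref = geometric_fba(chain)
        restricted = restrict_gene_flux(chain, "G1", 0.0, ref)
        deleted = apply_deletions(chain, {"G1"})
        assert solve_fba(restricted).objective_value == pytest.approx(
            solve_fba(deleted).objective_value, abs=1e-9
        )

    def test_fraction_one_recovers_wild_type(self, branched):
        ref = geometric_fba(branched)
        for gene in sorted(branched.genes):
            out = restrict_gene_flux(branched, gene, 1.0, ref)
            assert solve_fba(out).objective_value == pytest.approx(2.5, abs=1e-6)

    @pytest.mark.parametrize("fraction", [0.1, 0.5, 0.9])
    def test_chain_fitness_scales_linearly_with_fraction(self, chain, fraction):
        ref = geometric_fba(chain)
        out = restrict_gene_flux(chain, "G2", fraction, ref)
        assert solve_fba(out).objective_value == pytest.approx(10.0 * fraction)

    def test_restriction_never_raises_fitness(self, branched):
        ref = geometric_fba(branched)
        wt = solve_fba(branched).objective_value
        for gene in sorted(branched.genes):
            out = restrict_gene_flux(branched, gene, 0.5, ref)
            assert solve_fba(out).objective_value <= wt + 1e-9

    def test_unknown_gene_is_identity_with_warning(self, chain):
        ref = geometric_fba(chain)
        with pytest.warns(UserWarning, match="no-op"):
            out = restrict_gene_flux(chain, "GHOST", 0.5, ref)
        assert solve_fba(out).objective_value == pytest.approx(10.0)

    def test_fraction_outside_unit_interval_rejected(self, chain):
        ref = geometric_fba(chain)
        with pytest.raises(ValueError):
            restrict_gene_flux(chain, "G1", 1.5, ref)
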