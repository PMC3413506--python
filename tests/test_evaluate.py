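"""Deletion screens, confusion-matrix metrics, auxotrophy classification."""

import textwrap

import pytest

from fluxscreen import fixtures as fx
from fluxscreen.evaluate import (
    ConfusionMatrix,
    GeneLists,
    auxotrophy_screen,
    compare_models,
    read_gene_list,
    score_essentiality,
    single_deletion_screen,
)
from fluxscreen.perturb import MediumSpec


@pytest.fixture
def branched_lists():
    return GeneLists(
        essential=set(fx.BRANCHED_ESSENTIAL),
        auxotroph_inducing=set(fx.BRANCHED_AUXOTROPHIC),
    )


class TestScreen:
    def test_one_essential_one_redundant(self, branched):
        screen = single_deletion_screen(branched, genes=["GB", "GOR1"])
        assert screen.results["GB"] == (pytest.approx(0.0, abs=1e-9), False)
        assert screen.results["GOR1"][1] is True

    def test_or_pair_members_each_viable(self, branched):
        screen = single_deletion_screen(branched, genes=["GOR1", "GOR2"])
        assert screen.viable_genes == {"GOR1", "GOR2"}

    def test_full_screen_phenotypes(self, branched):
        screen = single_deletion_screen(branched)
        assert screen.viable_genes == {"GOR1", "GOR2", "GL1", "GL2"}
        assert screen.inviable_genes == {"GB", "GC1", "GC2", "GS", "GAux"}

    def test_results_invariant_under_gene_order(self, branched):
        fwd = single_deletion_screen(branched, genes=sorted(branched.genes))
        rev = single_deletion_screen(branched, genes=sorted(branched.genes, reverse=True))
        assert fwd.results == rev.results

    def test_inviable_wild_type_is_an_error(self, branched):
        starve = MediumSpec(bounds={}, name="nothing")
        with pytest.raises(ValueError, match="wild type"):
            single_deletion_screen(branched, starve)


class TestConfusionMatrix:
    def test_fixture_screen_scores_perfectly(self, branched, branched_lists):
        cm = score_essentiality(single_deletion_screen(branched), branched_lists)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (4, 0, 0, 5)
        assert cm.sensitivity == 1.0 and cm.specificity == 1.0
        assert cm.total == 9

    def test_reference_yeast_counts_reproduce_reported_metrics(self):
        # the published genome-scale screen: 684/20/113/101 over 918 genes
        cm = ConfusionMatrix(tp=684, fn=20, fp=113, tn=101)
        assert cm.total == 918
        assert cm.sensitivity == pytest.approx(0.972, abs=5e-4)
        assert cm.specificity == pytest.approx(0.472, abs=5e-4)
        assert cm.ppv == pytest.approx(0.858, abs=5e-4)
        assert cm.npv == pytest.approx(0.835, abs=5e-4)
        assert cm.combined_accuracy == pytest.approx(0.4588, abs=1e-3)

    def test_counts_always_sum_to_screened_genes(self, branched, branched_lists):
        screen = single_deletion_screen(branched)
        cm = score_essentiality(screen, branched_lists)
        assert cm.total == len(screen.results)

    def test_moving_a_gene_between_lists_preserves_row_sums(self, branched):
        screen = single_deletion_screen(branched)
        as_essential = GeneLists(essential={"GAux", "GB", "GC1", "GC2", "GS"})
        as_auxotroph = GeneLists(
            essential={"GB", "GC1", "GC2", "GS"}, auxotroph_inducing={"GAux"}
        )
        a = score_essentiality(screen, as_essential)
        b = score_essentiality(screen, as_auxotroph)
        assert (a.tp, a.fn, a.fp, a.tn) == (b.tp, b.fn, b.fp, b.tn)

    def test_unlisted_screen_is_all_positive(self, branched):
        cm = score_essentiality(single_deletion_screen(branched), GeneLists())
        assert cm.fp == cm.tn == 0
        assert cm.tp + cm.fn == 9


class TestAuxotrophy:
    def test_three_way_classification(self, branched):
        calls = auxotrophy_screen(branched, ["GAux", "GS", "GOR1"])
        by_gene = {c.gene: c.category for c in calls}
        assert by_gene == {
            "GAux": "auxotroph_confirmed",  # dead in minimal, rescued by supplement
            "GS": "inviable_in_supplemented",  # sterol cannot be supplied
            "GOR1": "viable_in_minimal",  # isoenzyme covers the loss
        }

    def test_rescued_growth_levels_recorded(self, branched):
        (call,) = auxotrophy_screen(branched, ["GAux"])
        assert call.objective_minimal == pytest.approx(0.0, abs=1e-9)
        assert call.objective_supplemented > 1.0


class TestGeneListIO(object):
    def test_comments_and_blanks_ignored(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text(
            textwrap.dedent(
                """\
                # essential genes
                YAL001C
                YBR002W  # trailing comment

                YCL003C
                """
            )
        )
        assert read_gene_list(str(p)) == {"YAL001C", "YBR002W", "YCL003C"}

    def test_unmatched_list_entries_warn_not_fail(self, branched):
        lists = GeneLists(essential={"GB", "NOT_IN_MODEL"})
        screen = single_deletion_screen(branched)
        with pytest.warns(UserWarning, match="absent from the screen"):
            cm = score_essentiality(screen, lists)
        assert cm.total == 9


class TestCompareModels:
    def test_identical_fixtures_give_identical_rows(self, branched_lists):
        a = fx.make_branched_fixture()
        b = fx.make_branched_fixture()
        table = compare_models([(a, branched_lists), (b, branched_lists)])
        assert len(table) == 2
        assert table.iloc[0].drop("model").equals(table.iloc[1].drop("model"))

    def test_census_and_metric_columns(self, branched, branched_lists):
        row = compare_models([(branched, branched_lists)]).iloc[0]
        assert row["n_genes"] == 9
        assert row["n_exchange"] == 8
        assert row["n_isa"] == 2
        assert row["n_metabolites"] == 17
        assert row["sensitivity"] == 1.0
        assert row["auxotroph_confirmed"] == 1
        assert row["blocked_fraction"] == pytest.approx(5 / 21)

    def test_broken_model_reported_not_fatal(self, branched, branched_lists):
        starved = branched.copy()
        starved.reaction("EX_glc").lower_bound = 0.0
        table = compare_models(
            [(starved, branched_lists), (branched, branched_lists)]
        )
        assert table.iloc[0]["error"] != ""
        assert table.iloc[1]["error"] == ""
        assert table.iloc[1]["sensitivity"] == 1.0
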