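"""The five-stage prioritization cascade: per-stage predicates, trace
conservation, and end-to-end behavior on synthetic trios."""

import pytest

from trioprio.filter_cascade import (
    CascadeConfig,
    biological_context_filter,
    common_variant_filter,
    confidence_filter,
    deleteriousness_filter,
    expand_items,
    genetic_model_filter,
    run_cascade,
)
from trioprio.variant_model import (
    AnnotationBundle,
    GeneNetwork,
    Pedigree,
    PedigreeMember,
)

from conftest import make_trio_variant, planted_key, rare_deleterious_annotation

CFG = CascadeConfig()


def one_item(variant):
    (item,) = expand_items([variant])
    return item


class TestConfidenceFilter:
    def test_carriers_at_threshold_kept(self, pedigree):
        v = make_trio_variant(quality=(50.0, 20.0, 20.0))
        kept, _ = confidence_filter([one_item(v)], pedigree, CFG)
        assert kept

    def test_all_carriers_below_threshold_removed(self, pedigree):
        v = make_trio_variant(quality=(50.0, 19.9, 19.9))
        kept, trace = confidence_filter([one_item(v)], pedigree, CFG)
        assert not kept
        assert trace.removal_stage(v.key()) == "confidence"

    def test_group_rule_or_vs_and(self, pedigree):
        # case carriers at 10, a control carrier at 25
        v = make_trio_variant(father=(0, 1), quality=(25.0, 10.0, 10.0))
        kept_any, _ = confidence_filter([one_item(v)], pedigree, CFG)
        assert kept_any
        cfg_and = CascadeConfig(quality_group_rule="all_groups")
        kept_all, _ = confidence_filter([one_item(v)], pedigree, cfg_and)
        assert not kept_all

    def test_no_quality_information_removed(self, pedigree):
        v = make_trio_variant(quality=(None, None, None))
        kept, trace = confidence_filter([one_item(v)], pedigree, CFG)
        assert not kept
        assert "no qualified call" in trace.entries[v.key()][-1][2]

    def test_noncarrier_quality_is_ignored(self, pedigree):
        # the father is hom-ref: his low quality must not matter
        v = make_trio_variant(quality=(1.0, 30.0, 30.0))
        kept, _ = confidence_filter([one_item(v)], pedigree, CFG)
        assert kept


class TestCommonVariantFilter:
    def run(self, bundle):
        v = make_trio_variant()
        return common_variant_filter([one_item(v)], {v.key(): bundle}, CFG)

    def test_inclusive_cutoff_removes(self):
        kept, _ = self.run(AnnotationBundle(af_1kg=0.031))
        assert not kept
        kept, _ = self.run(AnnotationBundle(af_1kg=0.03))
        assert not kept

    def test_below_cutoff_in_all_panels_kept(self):
        kept, _ = self.run(AnnotationBundle(af_1kg=0.029, af_cg69=0.029, af_esp=0.029))
        assert kept

    def test_any_single_panel_removes(self):
        kept, _ = self.run(AnnotationBundle(af_1kg=0.001, af_esp=0.5))
        assert not kept

    def test_all_missing_kept(self):
        kept, _ = self.run(AnnotationBundle())
        assert kept


class TestDeleteriousnessFilter:
    def run(self, bundle):
        v = make_trio_variant()
        return deleteriousness_filter([one_item(v)], {v.key(): bundle}, CFG)

    @pytest.mark.parametrize("bundle,expect_kept", [
        (AnnotationBundle(consequence="missense", sift_score=0.010), True),
        (AnnotationBundle(consequence="missense", sift_score=0.05), True),
        (AnnotationBundle(consequence="missense", sift_score=None), True),
        (AnnotationBundle(consequence="missense", sift_score=0.140), False),
        (AnnotationBundle(consequence="synonymous"), False),
        (AnnotationBundle(consequence="other"), False),
        (AnnotationBundle(consequence="frameshift"), True),
        (AnnotationBundle(consequence="inframe_indel"), True),
        (AnnotationBundle(consequence="stop_change"), True),
        (AnnotationBundle(consequence="structural"), True),
        (AnnotationBundle(consequence="splice_region", splice_intron_offset=2), True),
        (AnnotationBundle(consequence="splice_region", splice_intron_offset=-2), True),
        (AnnotationBundle(consequence="splice_region", splice_intron_offset=3), False),
        (AnnotationBundle(consequence="synonymous", clinical_assertion="pathogenic"), True),
        (AnnotationBundle(consequence="synonymous", clinical_assertion="possibly_pathogenic"), True),
        (AnnotationBundle(consequence="synonymous", clinical_assertion="unknown_significance"), True),
        (AnnotationBundle(consequence="synonymous", clinical_assertion="benign"), False),
        (AnnotationBundle(consequence="synonymous", gof_literature=True), True),
        (AnnotationBundle(consequence="synonymous", inferred_activating=True), True),
        (AnnotationBundle(consequence="synonymous", bsift_gof=True), True),
        (AnnotationBundle(consequence="synonymous", mirna_site=True), True),
    ])
    def test_criterion_disjunction(self, bundle, expect_kept):
        kept, _ = self.run(bundle)
        assert bool(kept) is expect_kept


class TestGeneticModelFilter:
    def test_dominant_pattern_kept(self, pedigree):
        v = make_trio_variant()  # mother het, daughter het, father hom-ref
        kept, _ = genetic_model_filter([one_item(v)], pedigree, CFG)
        assert kept

    def test_compound_het_counts_at_gene_level(self, pedigree):
        v1 = make_trio_variant(pos=100, mother=(0, 1), daughter=(0, 0))
        v2 = make_trio_variant(pos=200, mother=(0, 0), daughter=(0, 1))
        kept, _ = genetic_model_filter(expand_items([v1, v2]), pedigree, CFG)
        assert len(kept) == 2

    def test_control_carrier_removes_at_variant_level(self, pedigree):
        v1 = make_trio_variant(pos=100, father=(0, 1))
        v2 = make_trio_variant(pos=200)
        kept, trace = genetic_model_filter(expand_items([v1, v2]), pedigree, CFG)
        assert [i.key for i in kept] == [v2.key()]
        assert trace.removal_stage(v1.key()) == "genetic_analysis"

    def test_single_case_carrier_insufficient(self, pedigree):
        v = make_trio_variant(mother=(0, 1), daughter=(0, 0))
        kept, trace = genetic_model_filter([one_item(v)], pedigree, CFG)
        assert not kept
        assert "case carriers 1" in trace.entries[v.key()][-1][2]

    def test_geneless_variants_count_individually(self, pedigree):
        v1 = make_trio_variant(pos=100, gene="", mother=(0, 1), daughter=(0, 0))
        v2 = make_trio_variant(pos=200, gene="", mother=(0, 0), daughter=(0, 1))
        kept, _ = genetic_model_filter(expand_items([v1, v2]), pedigree, CFG)
        assert not kept  # no shared gene: each variant has one case carrier

    def test_too_few_cases_is_fatal(self):
        ped = Pedigree((PedigreeMember("A", "case", "mother"),
                        PedigreeMember("B", "control", "father")))
        with pytest.raises(ValueError, match="at least 2"):
            genetic_model_filter([], ped, CFG)


class TestBiologicalContextFilter:
    NET = GeneNetwork(edges=frozenset({("G", "D"), ("D", "H"), ("X", "Y")}),
                      disease_genes=frozenset({"D"}))

    @pytest.mark.parametrize("gene,expect_kept", [
        ("D", True),   # disease gene itself
        ("G", True),   # direct target edge G->D
        ("H", True),   # downstream of disease gene D->H
        ("X", False),  # connected, but not to the disease set
        ("Q", False),  # isolated
    ])
    def test_one_hop_rule(self, gene, expect_kept):
        v = make_trio_variant(gene=gene)
        kept, _ = biological_context_filter([one_item(v)], {}, self.NET)
        assert bool(kept) is expect_kept

    def test_no_gene_removed_with_reason(self):
        v = make_trio_variant(gene="")
        kept, trace = biological_context_filter([one_item(v)], {}, self.NET)
        assert not kept
        assert trace.entries[v.key()][-1][2] == "no gene"

    def test_gene_fallback_from_annotation(self):
        v = make_trio_variant(gene="")
        ann = {v.key(): AnnotationBundle(gene="D")}
        kept, _ = biological_context_filter([one_item(v)], ann, self.NET)
        assert kept


class TestRunCascade:
    NET = GeneNetwork(disease_genes=frozenset({"GENE1"}))

    def test_perturbing_frequency_removes_at_stage_two_only(self, pedigree):
        v = make_trio_variant()
        ann = {v.key(): rare_deleterious_annotation(af_1kg=0.05)}
        kept, trace = run_cascade([v], ann, pedigree, self.NET)
        assert not kept
        log = trace.entries[v.key()]
        assert [e[0] for e in log] == ["confidence", "common_variants"]
        assert log[-1][1] is False

    def test_empty_input(self, pedigree):
        kept, trace = run_cascade([], {}, pedigree, self.NET)
        assert kept == [] and trace.entries == {}

    def test_survivor_has_full_trace(self, pedigree):
        v = make_trio_variant()
        ann = {v.key(): rare_deleterious_annotation()}
        kept, trace = run_cascade([v], ann, pedigree, self.NET)
        assert kept == [v]
        assert trace.survived(v.key())

    def test_kept_set_invariant_under_input_permutation(self, trio_sim):
        kept_fwd, _ = run_cascade(trio_sim.variants, trio_sim.annotations,
                                  trio_sim.pedigree, trio_sim.network)
        kept_rev, _ = run_cascade(list(reversed(trio_sim.variants)),
                                  trio_sim.annotations, trio_sim.pedigree,
                                  trio_sim.network)
        assert {v.key() for v in kept_fwd} == {v.key() for v in kept_rev}

    def test_conservation_and_monotonicity(self, trio_sim):
        kept, trace = run_cascade(trio_sim.variants, trio_sim.annotations,
                                  trio_sim.pedigree, trio_sim.network)
        all_keys = [v.key() for v in trio_sim.variants]
        trace.check_conservation(all_keys, [v.key() for v in kept])
        counts = trace.stage_counts()
        entered = [counts[s]["entered"] for s in counts]
        assert entered == sorted(entered, reverse=True)  # stages only shrink

    def test_removed_variant_has_no_later_entries(self, trio_sim):
        _, trace = run_cascade(trio_sim.variants, trio_sim.annotations,
                               trio_sim.pedigree, trio_sim.network)
        for log in trace.entries.values():
            kept_flags = [kept for _, kept, _ in log]
            assert all(kept_flags[:-1])  # only the final entry may be a removal

    def test_adding_control_carrier_removes_exactly_that_variant(self, pedigree):
        v1 = make_trio_variant(pos=100)
        v2 = make_trio_variant(pos=200)
        v2_control = make_trio_variant(pos=200, father=(0, 1))
        ann = {v1.key(): rare_deleterious_annotation(),
               v2.key(): rare_deleterious_annotation()}
        kept_before, _ = run_cascade([v1, v2], ann, pedigree, self.NET)
        kept_after, _ = run_cascade([v1, v2_control], ann, pedigree, self.NET)
        assert {v.key() for v in kept_before} == {v1.key(), v2.key()}
        assert {v.key() for v in kept_after} == {v1.key()}
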