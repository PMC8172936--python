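"""Triage cascade: verdicts, provenance, tallies and partition properties."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from arprev import (
    AnalysisConfig,
    build_pathogenic_set,
    classify_variant,
    variant_landscape_summary,
)
from arprev.model import CLASSIFIER_MODES

from conftest import make_variant


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "kwargs,verdict,provenance",
        [
            # database assertion wins regardless of predictor disagreement
            (
                dict(clinvar="pathogenic", n_deleterious=0, n_tolerated=10),
                "pathogenic",
                "clinvar",
            ),
            # unanimous deleterious consensus for unannotated missense
            (
                dict(clinvar="absent", n_deleterious=10),
                "pathogenic",
                "missense_consensus",
            ),
            # one dissenting tool breaks unanimity
            (
                dict(clinvar="absent", n_deleterious=9, n_tolerated=1),
                "not_pathogenic",
                "none",
            ),
            # low-confidence LoF call is not trusted
            (
                dict(consequence="stop_gain", clinvar="absent", lof="low"),
                "not_pathogenic",
                "none",
            ),
            (
                dict(consequence="stop_gain", clinvar="absent", lof="high"),
                "pathogenic",
                "lof_high_confidence",
            ),
            # benign assertion excludes even a unanimous prediction
            (
                dict(clinvar="benign", n_deleterious=10),
                "excluded_benign",
                "none",
            ),
            # vus is routed to computational assessment
            (
                dict(clinvar="vus", n_deleterious=10),
                "pathogenic",
                "missense_consensus",
            ),
            (
                dict(clinvar="conflicting", n_deleterious=9, n_tolerated=0),
                "not_pathogenic",
                "none",
            ),
            # manual curation overrides the database label
            (
                dict(clinvar="pathogenic", curation_override="benign"),
                "excluded_benign",
                "none",
            ),
            (
                dict(call_confidence="low_confidence", clinvar="pathogenic"),
                "excluded_low_confidence",
                "none",
            ),
            # a missing call counts as non-deleterious under the strict policy
            (
                dict(clinvar="absent", n_deleterious=9, n_tolerated=0),
                "not_pathogenic",
                "none",
            ),
        ],
    )
    def test_ensemble_cascade(self, cfg, kwargs, verdict, provenance):
        call = classify_variant(make_variant(**kwargs), cfg)
        assert (call.verdict, call.provenance) == (verdict, provenance)

    def test_lenient_missing_policy_judges_called_tools(self):
        cfg = AnalysisConfig(missing_predictor_policy="lenient")
        v = make_variant(clinvar="absent", n_deleterious=7, n_tolerated=0)
        assert classify_variant(v, cfg).verdict == "pathogenic"
        v = make_variant(clinvar="absent", n_deleterious=0, n_tolerated=0)
        assert classify_variant(v, cfg).verdict == "not_pathogenic"

    def test_mode_semantics(self):
        consensus_only = make_variant(clinvar="absent", n_deleterious=10)
        clinvar_only_v = make_variant(clinvar="pathogenic", n_tolerated=10)
        confirmed = make_variant(clinvar="pathogenic", n_deleterious=10)

        def verdict(v, mode):
            return classify_variant(v, AnalysisConfig(classifier_mode=mode)).verdict

        assert verdict(consensus_only, "clinvar_only") == "not_pathogenic"
        assert verdict(consensus_only, "predictions_only") == "pathogenic"
        assert verdict(clinvar_only_v, "clinvar_plus") == "not_pathogenic"
        assert verdict(confirmed, "clinvar_plus") == "pathogenic"
        assert verdict(clinvar_only_v, "predictions_only") == "not_pathogenic"


class TestBuildPathogenicSet:
    def test_one_variant_per_provenance(self, cfg):
        variants = [
            make_variant(variant_id="chr1:1:A:T", clinvar="pathogenic"),
            make_variant(
                variant_id="chr1:2:A:T", consequence="frameshift", lof="high"
            ),
            make_variant(variant_id="chr1:3:A:T", n_deleterious=10),
        ]
        pset = build_pathogenic_set(variants, cfg)
        assert pset.n_pathogenic == 3
        assert pset.tally["clinvar"] == 1
        assert pset.tally["lof_high_confidence"] == 1
        assert pset.tally["missense_consensus"] == 1

    def test_all_benign_yields_empty_set(self, cfg):
        variants = [
            make_variant(variant_id=f"chr1:{i}:A:T", clinvar="benign")
            for i in range(5)
        ]
        pset = build_pathogenic_set(variants, cfg)
        assert pset.n_pathogenic == 0
        assert pset.tally["removed_benign"] == 5

    def test_empty_input(self, cfg):
        pset = build_pathogenic_set([], cfg)
        assert pset.n_pathogenic == 0
        assert pset.tally["total"] == 0

    def test_tally_matches_planted_truth_at_zero_noise(self):
        from arprev import SimulationConfig, generate_cohort

        variants, _, truth = generate_cohort(
            SimulationConfig(n_diseases=8).noiseless(), seed=5
        )
        pset = build_pathogenic_set(variants, AnalysisConfig())
        assert pset.n_pathogenic == int(truth.variants.true_pathogenic.sum())


class TestPartitionProperties:
    def test_verdicts_partition_input_per_mode(self, small_cohort):
        variants, _, _ = small_cohort
        for mode in CLASSIFIER_MODES:
            cfg = AnalysisConfig(classifier_mode=mode)
            pset = build_pathogenic_set(variants, cfg)
            tally = pset.tally
            assert (
                tally["pathogenic"]
                + tally["removed_benign"]
                + tally["removed_low_confidence"]
                + tally["not_pathogenic"]
                == len(variants)
                == tally["total"]
            )

    def test_clinvar_plus_nested_in_clinvar_only(self, small_cohort):
        variants, _, _ = small_cohort
        plus = {
            v.variant_id
            for v in build_pathogenic_set(
                variants, AnalysisConfig(classifier_mode="clinvar_plus")
            ).all_variants()
        }
        only = {
            v.variant_id
            for v in build_pathogenic_set(
                variants, AnalysisConfig(classifier_mode="clinvar_only")
            ).all_variants()
        }
        assert plus <= only

    def test_lowering_consensus_never_shrinks_set(self, small_cohort):
        variants, _, _ = small_cohort
        previous: set = set()
        for consensus in range(10, 0, -1):
            cfg = AnalysisConfig(required_consensus=consensus)
            current = {
                v.variant_id
                for v in build_pathogenic_set(variants, cfg).all_variants()
            }
            assert previous <= current
            previous = current

    def test_row_order_invariance(self, small_cohort, cfg):
        variants, _, _ = small_cohort
        shuffled = list(variants)
        random.Random(3).shuffle(shuffled)
        calls_a = sorted(
            (c.variant_id, c.verdict)
            for c in (classify_variant(v, cfg) for v in variants)
        )
        calls_b = sorted(
            (c.variant_id, c.verdict)
            for c in (classify_variant(v, cfg) for v in shuffled)
        )
        assert calls_a == calls_b

    @given(
        n_deleterious=st.integers(0, 10),
        n_tolerated=st.integers(0, 10),
        consensus=st.integers(1, 10),
    )
    @settings(derandomize=True, max_examples=100)
    def test_consensus_rule_monotone_in_evidence(
        self, n_deleterious, n_tolerated, consensus
    ):
        if n_deleterious + n_tolerated > 10:
            n_tolerated = 10 - n_deleterious
        cfg = AnalysisConfig(required_consensus=consensus)
        v = make_variant(n_deleterious=n_deleterious, n_tolerated=n_tolerated)
        verdict = classify_variant(v, cfg).verdict
        expected = n_tolerated == 0 and n_deleterious >= consensus
        assert (verdict == "pathogenic") == expected


class TestLandscape:
    def test_singletons_and_bins(self, cfg):
        variants = [
            # two singletons (global AC == 1)
            make_variant(variant_id="chr1:1:A:T", clinvar="pathogenic",
                         ac={"NFE": 1}, an={"NFE": 100000}),
            make_variant(variant_id="chr1:2:A:T", clinvar="pathogenic",
                         ac={"NFE": 1}, an={"NFE": 100000}),
            make_variant(variant_id="chr1:3:A:T", clinvar="pathogenic",
                         ac={"NFE": 5000}, an={"NFE": 100000}),  # 5% -> top bin
            make_variant(variant_id="chr1:4:A:T", clinvar="pathogenic",
                         ac={"NFE": 50}, an={"NFE": 100000}),  # 0.05%
            make_variant(variant_id="chr1:5:A:T", clinvar="benign",
                         ac={"NFE": 2}, an={"NFE": 100000}),
            make_variant(variant_id="chr1:6:A:T", consequence="synonymous",
                         ac={"NFE": 9}, an={"NFE": 100000}),
        ]
        pset = build_pathogenic_set(variants, cfg)
        summary = variant_landscape_summary(variants, pset)
        assert summary.n_singletons == 2
        assert summary.maf_bin_counts[">=1%"] == 1
        assert summary.maf_bin_counts["0.01-0.1%"] == 1
        assert summary.consequence_counts_all["synonymous"] == 1
        assert summary.per_gene_counts["GENE1"] == 4
        assert sum(summary.consequence_counts_pathogenic.values()) == 4
        fractions = summary.consequence_fractions(pathogenic=True)
        assert fractions["missense"] == pytest.approx(1.0)

    def test_empty_set_all_zero(self, cfg):
        pset = build_pathogenic_set([], cfg)
        summary = variant_landscape_summary([], pset)
        assert summary.n_singletons == 0
        assert sum(summary.maf_bin_counts.values()) == 0
        assert summary.to_frame().empty

    def test_all_common_variants_fill_top_bin(self, cfg):
        variants = [
            make_variant(variant_id=f"chr1:{i}:A:T", clinvar="pathogenic",
                         ac={"NFE": 2000 + i}, an={"NFE": 100000})
            for i in range(4)
        ]
        pset = build_pathogenic_set(variants, cfg)
        summary = variant_landscape_summary(variants, pset)
        assert summary.maf_bin_counts[">=1%"] == 4
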