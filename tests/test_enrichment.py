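"""Null model construction, the permutation engine against its closed-form
binomial oracle, significance rules and key-mutation extraction."""

import numpy as np
import pytest

import aleflow as af
from aleflow.annotations import AnnotationFramework, GenomicFeature
from aleflow.enrichment import (
    REMAINDER_ID,
    EnrichmentResult,
    NullModel,
    bonferroni,
    build_null_model,
    exact_tail_oracle,
    identify_key_mutations,
    key_mutation_proportions,
    observed_counts,
    permutation_test,
    run_enrichment,
)
from aleflow.errors import ConfigurationError, FeatureLookupError
from aleflow.mapping import MutatedFeatureInstance
from conftest import make_mutation


def single_feature_null(p):
    return NullModel("genomic_feature", ("f", REMAINDER_ID),
                     np.array([p, 1 - p]))


class TestNullModel:
    def test_single_gene_probabilities(self):
        fw = AnnotationFramework(
            genome_length=1000,
            features={"g": GenomicFeature("g", "gene", 0, 100)},
        )
        null = build_null_model(fw, "genomic_feature")
        probs = dict(zip(null.feature_ids, null.probabilities))
        assert probs["g"] == pytest.approx(0.1)
        assert probs[REMAINDER_ID] == pytest.approx(0.9)

    def test_full_coverage_scale_has_no_remainder(self, toy_framework):
        null = build_null_model(toy_framework, "gene_and_intergenic")
        assert REMAINDER_ID not in null.feature_ids
        assert null.probabilities.sum() == pytest.approx(1.0)

    def test_overlapping_features_renormalized(self):
        fw = AnnotationFramework(
            genome_length=1000,
            features={
                "a": GenomicFeature("a", "gene", 0, 100),
                "b": GenomicFeature("b", "TFBS", 50, 150),
            },
        )
        null = build_null_model(fw, "genomic_feature")
        probs = dict(zip(null.feature_ids, null.probabilities))
        # raw 0.1, 0.1, remainder (1000-150)/1000 = 0.85; renormalized by 1.05
        assert probs["a"] == pytest.approx(0.1 / 1.05)
        assert probs["b"] == pytest.approx(0.1 / 1.05)
        assert probs[REMAINDER_ID] == pytest.approx(0.85 / 1.05)

    def test_scale_without_features_is_configuration_error(self):
        fw = AnnotationFramework(
            genome_length=100,
            features={"g": GenomicFeature("g", "gene", 0, 50)},
        )
        with pytest.raises(ConfigurationError):
            build_null_model(fw, "operon")


class TestPermutationTest:
    def test_observed_zero_gives_p_one(self):
        p = permutation_test(single_feature_null(0.1), 5, {"f": 0}, 1000, seed=1)
        assert p["f"] == 1.0

    def test_certain_event_gives_p_one(self):
        null = NullModel("x", ("whole",), np.array([1.0]))
        p = permutation_test(null, 5, {"whole": 5}, 1000, seed=1)
        assert p["whole"] == 1.0

    def test_rare_tail_matches_smoothed_floor(self):
        # P(X>=5 | n=5, p=0.1) = 1e-5: essentially no iteration reaches it,
        # so the add-one smoothed p sits at 1/10001
        p = permutation_test(single_feature_null(0.1), 5, {"f": 5}, 10_000, seed=2)
        assert p["f"] == pytest.approx(1 / 10001, abs=3 / 10001)

    def test_deterministic_given_seed(self):
        null = single_feature_null(0.2)
        a = permutation_test(null, 20, {"f": 6}, 2000, seed=9)
        b = permutation_test(null, 20, {"f": 6}, 2000, seed=9)
        assert a == b

    def test_p_non_increasing_in_observed_count(self):
        null = single_feature_null(0.3)
        ps = [
            permutation_test(null, 20, {"f": k}, 5000, seed=4)["f"]
            for k in range(0, 21)
        ]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_unknown_feature_is_key_error(self):
        with pytest.raises(FeatureLookupError):
            permutation_test(single_feature_null(0.1), 5, {"nope": 1}, 100, seed=0)


class TestOracleAndCorrection:
    @pytest.mark.parametrize(
        "p,n,k,expected",
        [
            (0.1, 5, 0, 1.0),
            (0.1, 5, 5, 1e-5),
            (0.5, 2, 1, 0.75),
        ],
    )
    def test_binomial_tail_closed_forms(self, p, n, k, expected):
        assert exact_tail_oracle(p, n, k) == pytest.approx(expected)

    def test_invalid_oracle_ranges_rejected(self):
        with pytest.raises(ValueError):
            exact_tail_oracle(1.5, 5, 1)
        with pytest.raises(ValueError):
            exact_tail_oracle(0.5, 5, 6)

    @pytest.mark.parametrize(
        "p,m,expected", [(0.01, 10, 0.1), (0.5, 10, 1.0), (0.3, 1, 0.3)]
    )
    def test_bonferroni(self, p, m, expected):
        assert bonferroni([p], m)[0] == pytest.approx(expected)


class TestSignificanceRules:
    def _enrich(self, fw, instances, n):
        return run_enrichment(fw, instances, n, "genomic_feature",
                              iterations=2000, seed=3)

    def test_single_mutation_never_significant(self):
        fw = AnnotationFramework(
            genome_length=100_000,
            features={"g": GenomicFeature("g", "gene", 0, 10)},
        )
        inst = [MutatedFeatureInstance(make_mutation(5).key, "g",
                                       "genomic_feature")]
        res = self._enrich(fw, inst, 1)
        row = res.table.set_index("feature_id").loc["g"]
        assert row["p_corrected"] < 0.05  # 10 nt target, wildly enriched
        assert not row["significant"]  # but observed_count == 1

    def test_two_mutations_below_alpha_significant(self):
        fw = AnnotationFramework(
            genome_length=100_000,
            features={"g": GenomicFeature("g", "gene", 0, 10)},
        )
        inst = [
            MutatedFeatureInstance(make_mutation(5, ale_id=a).key, "g",
                                   "genomic_feature")
            for a in ("a1", "a2")
        ]
        res = self._enrich(fw, inst, 2)
        assert res.significant_features == {"g"}

    def test_remainder_never_flagged(self):
        fw = AnnotationFramework(
            genome_length=1000,
            features={"g": GenomicFeature("g", "gene", 0, 10)},
        )
        inst = [
            MutatedFeatureInstance(make_mutation(500 + i, ale_id=f"a{i}").key,
                                   REMAINDER_ID, "genomic_feature")
            for i in range(50)
        ]
        res = self._enrich(fw, inst, 50)
        assert res.significant_features == set()

    def test_observed_counts_once_per_mutation_per_feature(self):
        key = make_mutation(5).key
        inst = [
            MutatedFeatureInstance(key, "g", "genomic_feature"),
            MutatedFeatureInstance(key, "g", "genomic_feature"),
            MutatedFeatureInstance(make_mutation(6, ale_id="a2").key, "g",
                                   "genomic_feature"),
        ]
        assert observed_counts(inst, "genomic_feature") == {"g": 2}


class TestKeyMutations:
    def _fake_result(self, scale, significant_ids):
        import pandas as pd

        table = pd.DataFrame(
            [(fid, 100, 3, 0.0001, 0.001, True) for fid in significant_ids],
            columns=["feature_id", "length_nt", "observed_count", "p_raw",
                     "p_corrected", "significant"],
        )
        return EnrichmentResult(scale, table, 1000, 0, 3)

    def test_operon_significance_rescues_gene_mutation(self, toy_framework):
        mut = make_mutation(200)  # gA -> tu1 -> o1
        inst = af.propagate_to_scales([], toy_framework, [mut])
        results = {"operon": self._fake_result("operon", ["o1"])}
        kms = identify_key_mutations(inst, results, "exp01")
        assert kms.keys == {mut.key}
        assert ("operon", "o1") in kms.mutations[mut.key]

    def test_mutation_with_no_significant_features_not_key(self, toy_framework):
        mut = make_mutation(200)
        inst = af.propagate_to_scales([], toy_framework, [mut])
        kms = identify_key_mutations(inst, {}, "exp01")
        assert kms.keys == set()

    def test_dropping_a_scale_never_adds_keys(self, toy_framework):
        muts = [make_mutation(200), make_mutation(70, ale_id="a2")]
        inst = af.propagate_to_scales([], toy_framework, muts)
        full = {
            "operon": self._fake_result("operon", ["o1"]),
            "genomic_feature": self._fake_result("genomic_feature", ["pX"]),
        }
        reduced = {"genomic_feature": full["genomic_feature"]}
        keys_full = identify_key_mutations(inst, full).keys
        keys_reduced = identify_key_mutations(inst, reduced).keys
        assert keys_reduced <= keys_full


class TestKeyProportions:
    def test_everything_key_gives_one_everywhere(self, toy_framework):
        mut = make_mutation(200)
        inst = af.propagate_to_scales([], toy_framework, [mut])
        results = {
            "genomic_feature": TestKeyMutations()._fake_result(
                "genomic_feature", ["gA"]
            )
        }
        props = key_mutation_proportions(inst, results)
        assert (props["proportion"] == 1.0).all()

    def test_no_significance_gives_zero_everywhere(self, toy_framework):
        inst = af.propagate_to_scales([], toy_framework, [make_mutation(200)])
        props = key_mutation_proportions(inst, {})
        assert (props["proportion"] == 0.0).all()

    def test_operon_only_plant_raises_proportion_at_broad_prefix(
        self, toy_framework
    ):
        muts = [make_mutation(200), make_mutation(450, ale_id="a2")]
        inst = af.propagate_to_scales([], toy_framework, muts)
        results = {"regulon": TestKeyMutations()._fake_result("regulon", ["R1"])}
        props = key_mutation_proportions(inst, results).set_index("up_to_scale")
        assert props.loc["genomic_feature", "proportion"] == 0.0
        assert props.loc["regulon", "proportion"] == 1.0
        assert props.loc["COG", "proportion"] == 1.0
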