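"""Recall metrics, exact/soft field matching, accuracy aggregation, and
difficulty binning."""

import math
from collections import Counter

import numpy as np
import pytest

from litmine.backends import HashedNgramEmbedder
from litmine.corpus_model import ArmRecord, ParticipantValue
from litmine.errors import UndefinedMetricError
from litmine.evaluation import (FieldAccuracyReport, RecallReport,
                                bin_by_truth_count, exact_numeric_match,
                                field_accuracy, recall_at_k,
                                recall_at_truth_size, soft_text_match,
                                text_similarity)
from litmine.extraction import (ArmDesignResult, CharacteristicsResult,
                                DEFAULT_CHARACTERISTICS_FIELDS,
                                ParticipantStatsResult, TrialResultResult)


class TestRecall:
    def test_forced_count(self):
        assert recall_at_k(["a", "x", "b"], {"a", "b"}, k=2) == 0.5

    def test_saturation(self):
        assert recall_at_k(["a", "b", "x"], {"a", "b"}, k=3) == 1.0

    def test_short_list_uses_whole_list(self):
        assert recall_at_k(["a"], {"a", "b"}, k=10) == 0.5

    def test_empty_truth_is_an_error(self):
        with pytest.raises(UndefinedMetricError):
            recall_at_k(["a"], set(), 1)
        with pytest.raises(UndefinedMetricError):
            recall_at_truth_size(["a"], set())

    def test_matches_brute_force_for_all_k(self):
        rng = np.random.default_rng(42)
        ids = [f"s{i}" for i in range(100)]
        for _ in range(20):
            ranked = list(rng.permutation(ids))
            truth = set(rng.choice(ids, size=int(rng.integers(1, 30)),
                                   replace=False))
            for k in range(1, 101):
                expected = sum(1 for sid in ranked[:k] if sid in truth) \
                    / len(truth)
                assert recall_at_k(ranked, truth, k) == expected
            assert recall_at_truth_size(ranked, truth) == \
                recall_at_k(ranked, truth, len(truth))

    def test_non_decreasing_in_k(self):
        rng = np.random.default_rng(7)
        ranked = [f"s{i}" for i in rng.permutation(50)]
        truth = {f"s{i}" for i in range(10)}
        recalls = [recall_at_k(ranked, truth, k) for k in range(1, 51)]
        assert recalls == sorted(recalls)

    def test_perfect_and_reversed_oracle_rankings(self):
        truth = {f"t{i}" for i in range(5)}
        pool = sorted(truth) + [f"d{i}" for i in range(50)]
        assert recall_at_truth_size(pool, truth) == 1.0
        assert recall_at_truth_size(pool[::-1], truth) == 0.0


class TestExactNumericMatch:
    @pytest.mark.parametrize("pred,truth,expected", [
        ("1,204", 1204, True), ("12.50", 12.5, True),
        ("12.5 years", 12.5, True), ("85%", 85, True),
        (1204, 1204, True), ("1205", 1204, False),
        ("no value reported", 3.0, False),
    ])
    def test_normalization_table(self, pred, truth, expected):
        assert exact_numeric_match(pred, truth) is expected

    def test_nonfinite_truth_rejected(self):
        with pytest.raises(ValueError):
            exact_numeric_match("1", math.nan)


def _cosine_oracle(a: str, b: str) -> float:
    """Hand-computed cosine over character-3-gram counts."""
    ca = Counter(HashedNgramEmbedder.ngrams(a))
    cb = Counter(HashedNgramEmbedder.ngrams(b))
    dot = sum(ca[g] * cb[g] for g in ca)
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    return dot / (na * nb)


class TestSoftTextMatch:
    def test_identical_strings_match(self):
        assert text_similarity("heart failure", "heart failure") == 1.0
        assert soft_text_match("heart failure", "heart failure")

    def test_disjoint_strings_do_not_match(self):
        assert text_similarity("warfarin", "placebo") == 0.0
        assert not soft_text_match("warfarin", "placebo")

    @pytest.mark.parametrize("a,b", [
        ("atrial fibrillation", "atrial flutter"),
        ("heart failure", "heart failure with reduced ejection"),
        ("metformin arm", "metformin group"),
    ])
    def test_cosine_agrees_with_hand_computed_value(self, a, b):
        assert text_similarity(a, b) == pytest.approx(_cosine_oracle(a, b),
                                                      abs=1e-12)

    def test_symmetry_and_reflexivity(self):
        pairs = [("aspirin therapy", "aspirin treatment"),
                 ("stroke", "ischemic stroke")]
        for a, b in pairs:
            assert text_similarity(a, b) == text_similarity(b, a)
            assert text_similarity(a, a) == 1.0

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            soft_text_match("", "x")


class TestFieldAccuracy:
    def _char(self, enrollment, study_type="INTERVENTIONAL"):
        return CharacteristicsResult(values={
            "conditions": ["asthma"], "interventions": ["budesonide"],
            "enrollment": enrollment, "study_type": study_type})

    def test_identical_records_score_one(self):
        report = field_accuracy([(self._char(120.0), self._char(120.0))],
                                DEFAULT_CHARACTERISTICS_FIELDS)
        assert report.numeric_accuracy == 1.0
        assert report.text_accuracy == 1.0
        assert report.overall == 1.0

    def test_numeric_and_text_errors_stay_separated(self):
        pred = CharacteristicsResult(values={
            "conditions": ["asthma"], "interventions": ["budesonide"],
            "enrollment": 999.0, "study_type": "INTERVENTIONAL"})
        report = field_accuracy([(pred, self._char(120.0))],
                                DEFAULT_CHARACTERISTICS_FIELDS)
        assert report.numeric_accuracy == 0.0
        assert report.text_accuracy == 1.0

    def test_categorical_fields_require_exact_equality(self):
        pred = self._char(120.0, study_type="INTERVENTIONAL STUDY")
        report = field_accuracy([(pred, self._char(120.0))],
                                DEFAULT_CHARACTERISTICS_FIELDS)
        assert report.text_correct == report.text_total - 1

    def test_arms_align_by_label_not_position(self):
        a = ArmRecord(label="drug arm", arm_type="EXPERIMENTAL",
                      description="d", intervention_names=["drug"])
        b = ArmRecord(label="placebo arm", arm_type="COMPARATOR",
                      description="p", intervention_names=["placebo"])
        report = field_accuracy(
            [(ArmDesignResult(arms=[b, a]), ArmDesignResult(arms=[a, b]))],
            "arm_design")
        assert report.overall == 1.0

    def test_participant_results_align_by_group_id(self):
        r0 = ParticipantValue(group_id="BG000", value=61.0)
        r1 = ParticipantValue(group_id="BG001", value=59.5)
        report = field_accuracy(
            [(ParticipantStatsResult(results=[r1, r0]),
              ParticipantStatsResult(results=[r0, r1]))],
            "participant_stats")
        assert report.numeric_accuracy == 1.0

    def test_missing_prediction_entries_count_as_wrong(self):
        r0 = ParticipantValue(group_id="BG000", value=61.0)
        r1 = ParticipantValue(group_id="BG001", value=59.5)
        report = field_accuracy(
            [(ParticipantStatsResult(results=[r0]),
              ParticipantStatsResult(results=[r0, r1]))],
            "participant_stats")
        assert report.numeric_correct == 1 and report.numeric_total == 2

    def test_empty_results_are_an_error(self):
        with pytest.raises(UndefinedMetricError):
            field_accuracy([], "arm_design")

    def test_schema_mismatch_is_an_error(self):
        with pytest.raises(UndefinedMetricError, match="mismatch"):
            field_accuracy([(ArmDesignResult(arms=[]),
                             TrialResultResult(results=[]))], "arm_design")

    def test_merged_reports_pool_counts(self):
        a = FieldAccuracyReport(numeric_correct=1, numeric_total=2,
                                text_correct=3, text_total=3)
        b = FieldAccuracyReport(numeric_correct=0, numeric_total=1,
                                text_correct=0, text_total=2)
        merged = a.merged(b)
        assert merged.numeric_accuracy == pytest.approx(1 / 3)
        assert merged.text_accuracy == pytest.approx(3 / 5)


class TestBinning:
    @staticmethod
    def _report(rid, n_truth, recall):
        return RecallReport(review_id=rid, k=n_truth, recall=recall,
                            n_truth=n_truth)

    def test_single_bin_for_uniform_truth_counts(self):
        reports = [self._report(f"r{i}", 3, 0.5) for i in range(4)]
        bins = bin_by_truth_count(reports)
        assert list(bins) == ["[0-5)"]
        assert bins["[0-5)"].mean_recall == 0.5

    def test_means_match_hand_average_on_fixture(self):
        recalls = [0.2, 0.4, 0.6]
        reports = [self._report(f"a{i}", 3, r) for i, r in enumerate(recalls)]
        reports += [self._report("b", 7, 1.0)]
        bins = bin_by_truth_count(reports)
        assert bins["[0-5)"].mean_recall == pytest.approx(sum(recalls) / 3)
        assert bins["[5-10)"].mean_recall == 1.0

    def test_ci_omitted_below_ten_reviews(self):
        nine = [self._report(f"r{i}", 2, 0.5 + 0.01 * i) for i in range(9)]
        bins = bin_by_truth_count(nine)
        assert bins["[0-5)"].ci_low is None
        ten = nine + [self._report("r9", 2, 0.7)]
        bins = bin_by_truth_count(ten)
        assert bins["[0-5)"].ci_low is not None
        assert bins["[0-5)"].ci_low <= bins["[0-5)"].mean_recall \
            <= bins["[0-5)"].ci_high
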