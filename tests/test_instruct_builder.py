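"""Instruction-dataset construction: per-task builders, the negative-score
filter, review-level splits, and JSONL round-tripping."""

import json

import pytest

from litmine.backends import OracleBackend, parse_context
from litmine.boolean_query import parse_pubmed
from litmine.corpus_model import SyntheticConfig, generate_corpus
from litmine.errors import ConfigurationError
from litmine.instruct_builder import (InstructionRecord, RecordMeta,
                                      build_eligibility_instructions,
                                      build_extraction_instructions,
                                      build_search_instructions,
                                      dataset_stats, export_jsonl,
                                      import_jsonl, split_dataset)
from litmine.query_synthesis import filter_by_recall


@pytest.fixture(scope="module")
def ten_review_corpus():
    return generate_corpus(SyntheticConfig(
        n_reviews=10, included_per_review=4, distractors_per_review=20,
        overlap_rate=0.2, seed=3))


@pytest.fixture(scope="module")
def ten_review_oracle(ten_review_corpus):
    return OracleBackend(ten_review_corpus)


class TestSearchInstructions:
    def test_one_record_per_review_when_all_terms_match(
            self, ten_review_corpus, ten_review_oracle):
        records = build_search_instructions(ten_review_corpus,
                                            ten_review_oracle)
        assert len(records) == len(ten_review_corpus.reviews)
        assert {r.meta.review_id for r in records} == \
            set(ten_review_corpus.inclusion_truth)

    def test_outputs_reparse_with_recall_above_threshold(
            self, ten_review_corpus, ten_review_oracle):
        for record in build_search_instructions(ten_review_corpus,
                                                ten_review_oracle):
            query = parse_pubmed(record.output)
            decision = filter_by_recall(
                query, ten_review_corpus,
                ten_review_corpus.truth(record.meta.review_id))
            assert decision.recall >= 0.2

    def test_review_with_failing_query_is_skipped(self, ten_review_corpus,
                                                  ten_review_oracle):
        skip_rid = ten_review_corpus.reviews[0].review_id
        skip_sids = set(ten_review_corpus.inclusion_truth[skip_rid])

        class BadTermsOracle(OracleBackend):
            def complete(self, prompt, seed=0, **kw):
                ctx = parse_context(prompt)
                if ctx.get("study_id") in skip_sids:
                    return json.dumps({"population": ["zzzunmatched"],
                                       "intervention": ["zzzmissing"]})
                return super().complete(prompt, seed=seed, **kw)

        records = build_search_instructions(ten_review_corpus,
                                            BadTermsOracle(ten_review_corpus))
        assert skip_rid not in {r.meta.review_id for r in records}
        assert len(records) == len(ten_review_corpus.reviews) - 1


class TestEligibilityInstructions:
    def test_oracle_analyses_are_never_dropped(self, ten_review_corpus,
                                               ten_review_oracle):
        records = build_eligibility_instructions(
            ten_review_corpus, ten_review_oracle, pool_size=40, seed=0)
        positives = [r for r in records if r.meta.study_id
                     in ten_review_corpus.truth(r.meta.review_id)]
        assert len(positives) == sum(
            len(ids) for ids in ten_review_corpus.inclusion_truth.values())

    def test_negative_score_included_records_dropped_and_only_those(
            self, ten_review_corpus):
        corpus = ten_review_corpus
        victim_rid = corpus.reviews[0].review_id
        victim_sid = corpus.inclusion_truth[victim_rid][0]

        class SabotagedOracle(OracleBackend):
            def complete(self, prompt, seed=0, **kw):
                ctx = parse_context(prompt)
                if (ctx.get("task") == "eligibility"
                        and ctx.get("study_id") == victim_sid):
                    return json.dumps({"assessments": [
                        {"label": "NO", "rationale": "injected"}
                        for _ in ctx["elements"]]})
                return super().complete(prompt, seed=seed, **kw)

        records = build_eligibility_instructions(
            corpus, SabotagedOracle(corpus), pool_size=40, seed=0)
        included = {sid for ids in corpus.inclusion_truth.values()
                    for sid in ids}
        kept_positive_ids = {r.meta.study_id for r in records
                             if r.meta.study_id
                             in corpus.truth(r.meta.review_id)}
        assert victim_sid not in kept_positive_ids
        assert kept_positive_ids == included - {victim_sid}

    def test_balanced_within_one_per_review(self, ten_review_corpus,
                                            ten_review_oracle):
        records = build_eligibility_instructions(
            ten_review_corpus, ten_review_oracle, pool_size=40, seed=0)
        for rid in ten_review_corpus.inclusion_truth:
            truth = ten_review_corpus.truth(rid)
            revs = [r for r in records if r.meta.review_id == rid]
            pos = sum(1 for r in revs if r.meta.study_id in truth)
            neg = len(revs) - pos
            assert abs(pos - neg) <= 1


class TestExtractionInstructions:
    def test_four_records_per_fully_populated_study(self, ten_review_corpus):
        records = build_extraction_instructions(ten_review_corpus)
        n_linked = sum(len(ids) for ids in
                       ten_review_corpus.inclusion_truth.values())
        assert len(records) == 4 * n_linked

    def test_emission_is_presence_driven(self, ten_review_corpus):
        from litmine.corpus_model import LinkedCorpus
        corpus = LinkedCorpus.from_json(ten_review_corpus.to_json())
        sid = corpus.inclusion_truth[corpus.reviews[0].review_id][0]
        corpus.study(sid).registry_truth.outcome_results = []
        records = build_extraction_instructions(corpus)
        tasks_for_sid = {r.task for r in records if r.meta.study_id == sid}
        assert tasks_for_sid == {"characteristics", "arm_design",
                                 "participant_stats"}

    def test_outputs_deserialize_as_json(self, ten_review_corpus):
        for record in build_extraction_instructions(ten_review_corpus):
            payload = json.loads(record.output)
            assert isinstance(payload, dict)


class TestSplit:
    def _records(self, n_reviews):
        return [InstructionRecord(
            task="search_query", instruction="i", input="in", output="out",
            meta=RecordMeta(review_id=f"R{i}")) for i in range(n_reviews)]

    def test_ten_reviews_split_exactly_six_two_two(self):
        records = split_dataset(self._records(10), seed=0)
        by_split = {}
        for r in records:
            by_split.setdefault(r.meta.split, set()).add(r.meta.review_id)
        assert sorted(len(v) for v in by_split.values()) == [2, 2, 6]
        assert len(by_split["train"]) == 6

    def test_same_seed_reproduces_assignment(self):
        a = split_dataset(self._records(10), seed=5)
        b = split_dataset(self._records(10), seed=5)
        assert [r.meta.split for r in a] == [r.meta.split for r in b]

    def test_no_review_spans_two_splits(self, ten_review_corpus,
                                        ten_review_oracle):
        records = build_search_instructions(ten_review_corpus,
                                            ten_review_oracle)
        records += build_extraction_instructions(ten_review_corpus)
        split = split_dataset(records, seed=1)
        seen: dict[str, str] = {}
        for r in split:
            assert seen.setdefault(r.meta.review_id, r.meta.split) == \
                r.meta.split

    def test_too_few_reviews_is_an_error(self):
        with pytest.raises(ConfigurationError):
            split_dataset(self._records(2), seed=0)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ConfigurationError):
            split_dataset(self._records(10), ratios=(0.5, 0.2, 0.2), seed=0)


class TestJsonl:
    def _records(self):
        return split_dataset([InstructionRecord(
            task="eligibility", instruction="inst", input=f"in {i}",
            output="out", meta=RecordMeta(review_id=f"R{i}", study_id=f"s{i}"))
            for i in range(5)], seed=0)

    def test_line_count(self, tmp_path):
        path = tmp_path / "a.jsonl"
        export_jsonl(self._records(), path)
        assert len(path.read_text().splitlines()) == 5

    def test_round_trip_is_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        export_jsonl(self._records(), p1)
        export_jsonl(import_jsonl(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_import_reproduces_records(self, tmp_path):
        path = tmp_path / "a.jsonl"
        records = self._records()
        export_jsonl(records, path)
        assert import_jsonl(path) == records

    def test_empty_record_list_gives_empty_file(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        export_jsonl([], path)
        assert path.read_text() == ""


def test_dataset_stats_conservation(ten_review_corpus, ten_review_oracle):
    records = (build_search_instructions(ten_review_corpus,
                                         ten_review_oracle)
               + build_extraction_instructions(ten_review_corpus))
    stats = dataset_stats(records)
    assert stats["total"] == sum(stats["by_task"].values())
    assert stats["total"] == sum(stats["by_split"].values())
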