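"""Term extraction, query assembly, the recall filter, and ensemble
generation."""

import json

import pytest

from litmine.backends import FunctionBackend, NoisyOracleBackend, OracleBackend
from litmine.boolean_query import And, Or, Term, evaluate, retrieve
from litmine.corpus_model import PICOFrame, SyntheticConfig, generate_corpus
from litmine.errors import (AssemblyError, BackendOutputError,
                            GenerationError, UndefinedMetricError)
from litmine.evaluation import recall_at_k
from litmine.query_synthesis import (TermSet, assemble_query, ensemble_generate,
                                     extract_terms, filter_by_recall,
                                     generate_query)


def _json_backend(payload):
    return FunctionBackend(lambda prompt, seed: json.dumps(payload))


class TestExtractTerms:
    def test_oracle_returns_planted_terms(self, small_corpus, oracle):
        for sid, planted in small_corpus.planted_terms.items():
            ts = extract_terms(small_corpus.study(sid), oracle)
            assert ts.population_terms == planted.population
            assert ts.intervention_terms == planted.intervention

    def test_truncates_to_ten_terms(self, small_corpus):
        backend = _json_backend({
            "population": [f"p{i}" for i in range(12)],
            "intervention": ["i1"]})
        ts = extract_terms(small_corpus.studies[0], backend)
        assert ts.population_terms == [f"p{i}" for i in range(10)]

    def test_deduplicates_and_trims(self, small_corpus):
        backend = _json_backend({"population": [" a ", "a", "b"],
                                 "intervention": ["i", "", "i"]})
        ts = extract_terms(small_corpus.studies[0], backend)
        assert ts.population_terms == ["a", "b"]
        assert ts.intervention_terms == ["i"]

    def test_unparseable_output_carries_raw(self, small_corpus):
        backend = FunctionBackend(lambda p, s: "not json at all")
        with pytest.raises(BackendOutputError) as exc:
            extract_terms(small_corpus.studies[0], backend)
        assert exc.value.raw_output == "not json at all"


class TestAssembleQuery:
    def test_single_termset_structure(self):
        ts = TermSet(source_study_id="s", population_terms=["p1", "p2"],
                     intervention_terms=["i1"])
        query = assemble_query([ts])
        # S = (p1 AND p2) AND i1 once single-child groups collapse
        assert query == And((And((Term("p1"), Term("p2"))), Term("i1")))

    def test_two_termsets_give_two_or_children_per_clause(self):
        sets = [TermSet(source_study_id=f"s{i}",
                        population_terms=[f"p{i}a", f"p{i}b"],
                        intervention_terms=[f"i{i}a", f"i{i}b"])
                for i in range(2)]
        query = assemble_query(sets)
        sp, si = query.children
        assert isinstance(sp, Or) and len(sp.children) == 2
        assert isinstance(si, Or) and len(si.children) == 2

    def test_assembled_query_retrieves_every_source_study(
            self, small_corpus, oracle):
        for rid, truth_ids in small_corpus.inclusion_truth.items():
            sets = [extract_terms(small_corpus.study(sid), oracle)
                    for sid in truth_ids]
            hits = evaluate(assemble_query(sets), small_corpus)
            assert set(truth_ids) <= hits

    def test_term_order_within_study_does_not_change_matches(
            self, small_corpus, oracle):
        rid = small_corpus.reviews[0].review_id
        sets = [extract_terms(small_corpus.study(sid), oracle)
                for sid in small_corpus.inclusion_truth[rid]]
        reversed_sets = [
            TermSet(source_study_id=ts.source_study_id,
                    population_terms=ts.population_terms[::-1],
                    intervention_terms=ts.intervention_terms[::-1])
            for ts in sets]
        assert evaluate(assemble_query(sets), small_corpus) == \
            evaluate(assemble_query(reversed_sets), small_corpus)

    def test_empty_input_is_assembly_error(self):
        with pytest.raises(AssemblyError):
            assemble_query([])

    def test_or_connective_widens_matches(self, small_corpus, oracle):
        rid = small_corpus.reviews[0].review_id
        sets = [extract_terms(small_corpus.study(sid), oracle)
                for sid in small_corpus.inclusion_truth[rid]]
        strict = evaluate(assemble_query(sets, "and"), small_corpus)
        loose = evaluate(assemble_query(sets, "or"), small_corpus)
        assert strict <= loose


class TestFilterByRecall:
    def test_full_overlap_keeps(self, small_corpus, oracle):
        rid = small_corpus.reviews[0].review_id
        truth = small_corpus.truth(rid)
        sets = [extract_terms(small_corpus.study(sid), oracle)
                for sid in sorted(truth)]
        decision = filter_by_recall(assemble_query(sets), small_corpus, truth)
        assert decision.keep and decision.recall == 1.0

    def test_empty_truth_is_an_error(self, small_corpus):
        with pytest.raises(UndefinedMetricError):
            filter_by_recall(Term("x"), small_corpus, set())


class TestGenerateQuery:
    def test_oracle_query_has_full_recall(self, small_corpus, oracle):
        for review in small_corpus.reviews:
            query = generate_query(review.pico, oracle,
                                   review_id=review.review_id)
            decision = filter_by_recall(query, small_corpus,
                                        small_corpus.truth(review.review_id))
            assert decision.recall == 1.0

    def test_missing_intervention_group_is_generation_error(self):
        backend = _json_backend({"groups": [{"population": ["p"]}]})
        pico = PICOFrame(population="p", intervention="i")
        with pytest.raises(GenerationError):
            generate_query(pico, backend)

    def test_no_groups_is_generation_error(self):
        backend = _json_backend({"groups": []})
        with pytest.raises(GenerationError):
            generate_query(PICOFrame(population="p", intervention="i"),
                           backend)

    def test_fixed_backend_and_seed_give_identical_trees(
            self, small_corpus):
        backend = NoisyOracleBackend(small_corpus, error_rate=0.5, seed=3)
        review = small_corpus.reviews[0]
        q1 = generate_query(review.pico, backend, seed=9,
                            review_id=review.review_id)
        q2 = generate_query(review.pico, backend, seed=9,
                            review_id=review.review_id)
        assert q1 == q2


class TestEnsemble:
    def test_single_run_equals_generate_plus_retrieve(self, small_corpus,
                                                      oracle):
        review = small_corpus.reviews[0]
        rid = review.review_id
        direct = retrieve(generate_query(review.pico, oracle, seed=4,
                                         review_id=rid),
                          small_corpus, limit=100)
        assert ensemble_generate(review.pico, oracle, small_corpus,
                                 limit=100, n_runs=1, seed=4,
                                 review_id=rid) == direct

    def test_union_dedup_keeps_first_occurrence(self, small_corpus):
        runs = iter([json.dumps({"groups": [{"population": ["patients"],
                                             "intervention": ["warfarin"]}]}),
                     json.dumps({"groups": [{"population": ["patients"],
                                             "intervention": ["metformin"]}]})])
        backend = FunctionBackend(lambda p, s: next(runs))
        merged = ensemble_generate(
            PICOFrame(population="p", intervention="i"), backend,
            small_corpus, limit=50, n_runs=2, seed=0)
        assert len(merged) == len(set(merged))

    def test_ensemble_recall_dominates_best_single_run(self, small_corpus):
        review = small_corpus.reviews[0]
        rid = review.review_id
        truth = small_corpus.truth(rid)
        backend = NoisyOracleBackend(small_corpus, error_rate=0.5, seed=21)
        singles = []
        for run in range(5):
            hits = retrieve(generate_query(review.pico, backend, seed=run,
                                           review_id=rid),
                            small_corpus, limit=100)
            singles.append(recall_at_k(hits, truth, 100))
        merged = ensemble_generate(review.pico, backend, small_corpus,
                                   limit=100, n_runs=5, seed=0,
                                   review_id=rid)
        assert recall_at_k(merged, truth, 100) >= max(singles)

    def test_partial_failures_are_skipped(self, small_corpus):
        calls = {"n": 0}

        def flaky(prompt, seed):
            calls["n"] += 1
            if calls["n"] == 1:
                return "garbage"
            return json.dumps({"groups": [{"population": ["patients"],
                                           "intervention": ["care"]}]})

        merged = ensemble_generate(
            PICOFrame(population="p", intervention="i"),
            FunctionBackend(flaky), small_corpus, limit=50, n_runs=2, seed=0)
        assert merged  # second run succeeded

    def test_all_failures_raise(self, small_corpus):
        backend = FunctionBackend(lambda p, s: "garbage")
        with pytest.raises(GenerationError):
            ensemble_generate(PICOFrame(population="p", intervention="i"),
                              backend, small_corpus, limit=50, n_runs=3,
                              seed=0)
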