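"""Instruction-dataset construction from a linked corpus.

Each instruction record is an (instruction, input, output) triple tagged
with its task and split.  Search records pair a review's PICO frame with a
query assembled from per-study keyword sets, kept only if its measured
recall on the review's target studies is at least 0.2.  Eligibility records
pair criteria+study content with criterion-level analyses; ground-truth
included studies whose generated analysis nevertheless aggregates to a
negative score are dropped as contradictory, and non-included candidates
are sampled one-per-positive so each review contributes a balanced set.
Extraction records embed the truncated document plus request fields as
input and the registry ground truth as output.  Splits are assigned at the
review level (6:2:2 by default) so no review leaks across train/dev/test.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel

from .backends import GenerativeBackend, PROMPTS
from .boolean_query import serialize_pubmed
from .corpus_model import LinkedCorpus, ReviewTopic, StudyRecord
from .errors import BackendOutputError, ConfigurationError, GenerationError
from .extraction import (DEFAULT_CHARACTERISTICS_FIELDS, _build_prompt,
                         participant_request_from_truth,
                         trial_result_request_from_truth, truncate_document)
from .query_synthesis import assemble_query, extract_terms, filter_by_recall
from .screening import assess_study, build_candidate_pool, criteria_from_review

logger = logging.getLogger(__name__)

TASK_NAMES = ("search_query", "eligibility", "characteristics", "arm_design",
              "participant_stats", "trial_results")

_INSTRUCTIONS = {
    "search_query": ("Generate a boolean search query, with population and "
                     "intervention keyword groups, that retrieves the "
                     "studies relevant to the research question below."),
    "eligibility": ("Assess the candidate study against each eligibility "
                    "criterion, answering YES, PARTIAL, UNCERTAIN, or NO "
                    "with a rationale per criterion."),
    "characteristics": ("Extract the requested study characteristics from "
                        "the document."),
    "arm_design": "Extract the design of every study arm from the document.",
    "participant_stats": ("Extract the participant statistics requested "
                          "below from the document."),
    "trial_results": ("Extract the trial results requested below from the "
                      "document."),
}


class RecordMeta(BaseModel):
    review_id: Optional[str] = None
    study_id: Optional[str] = None
    split: Optional[Literal["train", "dev", "test"]] = None
    template_version: str = "v1"


class InstructionRecord(BaseModel):
    task: Literal["search_query", "eligibility", "characteristics",
                  "arm_design", "participant_stats", "trial_results"]
    instruction: str
    input: str
    output: str
    meta: RecordMeta


def _pico_block(review: ReviewTopic) -> str:
    p = review.pico
    return (f"Population: {p.population}\nIntervention: {p.intervention}\n"
            f"Comparator: {p.comparator}\nOutcome: {p.outcome}")


# ---------------------------------------------------------------------------
# Per-task builders
# ---------------------------------------------------------------------------

def build_search_instructions(corpus: LinkedCorpus,
                              backend: GenerativeBackend,
                              threshold: float = 0.2,
                              seed: int = 0) -> list[InstructionRecord]:
    """One record per review whose assembled query survives the recall
    filter; reviews with no surviving query are skipped with a logged
    reason."""
    records: list[InstructionRecord] = []
    for review in corpus.reviews:
        truth = corpus.truth(review.review_id)
        if not truth:
            logger.info("review %s has no target studies; skipped",
                        review.review_id)
            continue
        try:
            termsets = [extract_terms(corpus.study(sid), backend, seed=seed)
                        for sid in sorted(truth)]
            query = assemble_query(termsets)
        except BackendOutputError as err:
            logger.warning("term extraction failed for review %s: %s",
                           review.review_id, err)
            continue
        decision = filter_by_recall(query, corpus, truth, threshold)
        if not decision.keep:
            logger.info("review %s: query recall %.3f below %.2f; dropped",
                        review.review_id, decision.recall, threshold)
            continue
        records.append(InstructionRecord(
            task="search_query",
            instruction=_INSTRUCTIONS["search_query"],
            input=_pico_block(review),
            output=serialize_pubmed(query),
            meta=RecordMeta(review_id=review.review_id),
        ))
    return records


def _analysis_output(result) -> str:
    return json.dumps({
        "assessments": [{"label": a.label, "rationale": a.rationale}
                        for a in result.assessments],
        "final_score": result.final_score,
    }, sort_keys=True)


def build_eligibility_instructions(corpus: LinkedCorpus,
                                   backend: GenerativeBackend,
                                   pool_size: int = 2000,
                                   seed: int = 0,
                                   primary_hits: Optional[dict[str, list[str]]]
                                   = None) -> list[InstructionRecord]:
    """Balanced eligibility records per review.

    ``primary_hits`` optionally supplies precomputed search hits per review;
    otherwise pools are built from element fill queries alone.  Included
    studies whose generated analysis aggregates to a negative final score
    are dropped (the analysis contradicts the inclusion ground truth);
    non-included candidates are drawn uniformly at random, one per kept
    positive.
    """
    rng = np.random.default_rng(seed)
    records: list[InstructionRecord] = []
    n_dropped = 0
    for review in corpus.reviews:
        criteria = criteria_from_review(review)
        if not criteria:
            logger.warning("review %s has no criteria; skipped",
                           review.review_id)
            continue
        truth = corpus.truth(review.review_id)
        hits = (primary_hits or {}).get(review.review_id, [])
        pool = build_candidate_pool(review, corpus, hits, pool_size)
        positives: list[tuple[StudyRecord, str]] = []
        for sid in sorted(truth):
            study = corpus.study(sid)
            result = assess_study(criteria, study, backend,
                                  review_id=review.review_id, seed=seed)
            if result.final_score < 0:
                n_dropped += 1
                logger.info("included study %s of review %s dropped: "
                            "analysis score %.2f is negative",
                            sid, review.review_id, result.final_score)
                continue
            positives.append((study, _analysis_output(result)))
        negatives_pool = sorted(set(pool) - truth)
        n_neg = min(len(positives), len(negatives_pool))
        neg_ids = (rng.choice(negatives_pool, size=n_neg, replace=False)
                   if n_neg else [])
        criteria_text = "\n".join(f"[{c.element}/{c.role}] {c.text}"
                                  for c in criteria)
        for study, output in positives:
            records.append(InstructionRecord(
                task="eligibility",
                instruction=_INSTRUCTIONS["eligibility"],
                input=(f"Criteria:\n{criteria_text}\n\nTitle: {study.title}\n"
                       f"Abstract: {study.abstract}"),
                output=output,
                meta=RecordMeta(review_id=review.review_id,
                                study_id=study.study_id),
            ))
        for sid in neg_ids:
            study = corpus.study(str(sid))
            result = assess_study(criteria, study, backend,
                                  review_id=review.review_id, seed=seed)
            records.append(InstructionRecord(
                task="eligibility",
                instruction=_INSTRUCTIONS["eligibility"],
                input=(f"Criteria:\n{criteria_text}\n\nTitle: {study.title}\n"
                       f"Abstract: {study.abstract}"),
                output=_analysis_output(result),
                meta=RecordMeta(review_id=review.review_id,
                                study_id=study.study_id),
            ))
    if n_dropped:
        logger.info("eligibility builder dropped %d contradictory included-"
                    "study records", n_dropped)
    return records


def build_extraction_instructions(corpus: LinkedCorpus,
                                  budget_tokens: int = 30000
                                  ) -> list[InstructionRecord]:
    """One record per (study, extraction task) for which the linked registry
    record carries truth for that task."""
    owner: dict[str, str] = {}
    for rid, sids in corpus.inclusion_truth.items():
        for sid in sids:
            owner.setdefault(sid, rid)
    records: list[InstructionRecord] = []
    for study in corpus.studies:
        truth = study.registry_truth
        if study.kind != "publication" or truth is None:
            continue
        document = truncate_document(study, budget_tokens)
        meta = RecordMeta(review_id=owner.get(study.study_id),
                          study_id=study.study_id)
        if truth.conditions or truth.interventions or truth.study_type:
            records.append(InstructionRecord(
                task="characteristics",
                instruction=_INSTRUCTIONS["characteristics"],
                input=_build_prompt("characteristics",
                                    DEFAULT_CHARACTERISTICS_FIELDS, document),
                output=json.dumps({
                    "conditions": truth.conditions,
                    "interventions": truth.interventions,
                    "enrollment": truth.enrollment,
                    "study_type": truth.study_type,
                }, sort_keys=True),
                meta=meta))
        if truth.arms:
            records.append(InstructionRecord(
                task="arm_design",
                instruction=_INSTRUCTIONS["arm_design"],
                input=_build_prompt("arm_design", None, document),
                output=json.dumps(
                    {"arms": [a.model_dump() for a in truth.arms]},
                    sort_keys=True),
                meta=meta))
        if truth.participant_measures:
            pm = truth.participant_measures[0]
            records.append(InstructionRecord(
                task="participant_stats",
                instruction=_INSTRUCTIONS["participant_stats"],
                input=_build_prompt("participant_stats",
                                    participant_request_from_truth(pm),
                                    document),
                output=json.dumps(
                    {"results": [r.model_dump() for r in pm.results]},
                    sort_keys=True),
                meta=meta))
        if truth.outcome_results:
            tr = truth.outcome_results[0]
            records.append(InstructionRecord(
                task="trial_results",
                instruction=_INSTRUCTIONS["trial_results"],
                input=_build_prompt("trial_results",
                                    trial_result_request_from_truth(tr),
                                    document),
                output=json.dumps(
                    {"results": [r.model_dump() for r in tr.results]},
                    sort_keys=True),
                meta=meta))
    return records


# ---------------------------------------------------------------------------
# Splitting and serialization
# ---------------------------------------------------------------------------

def split_dataset(records: list[InstructionRecord],
                  ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> list[InstructionRecord]:
    """Assign train/dev/test splits at the review level.

    All records sharing a review id land in the same split; records with no
    review id form their own study-level groups.  Group counts follow the
    ratios by largest remainder, so a 10-review corpus splits exactly
    6/2/2.  The shuffle is seeded and reproducible.
    """
    if any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError("ratios must be nonnegative and sum to 1")
    groups: list[str] = []
    for r in records:
        key = r.meta.review_id or f"study:{r.meta.study_id}"
        if key not in groups:
            groups.append(key)
    n_splits = sum(1 for r in ratios if r > 0)
    if len(groups) < n_splits:
        raise ConfigurationError(
            f"need at least {n_splits} review groups to split, "
            f"got {len(groups)}")
    rng = np.random.default_rng(seed)
    order = [groups[i] for i in rng.permutation(len(groups))]
    n = len(order)
    raw = [r * n for r in ratios]
    counts = [int(x) for x in raw]
    remainders = sorted(range(3), key=lambda i: raw[i] - counts[i],
                        reverse=True)
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    assignment: dict[str, str] = {}
    start = 0
    for split, count in zip(("train", "dev", "test"), counts):
        for key in order[start:start + count]:
            assignment[key] = split
        start += count
    out: list[InstructionRecord] = []
    for r in records:
        key = r.meta.review_id or f"study:{r.meta.study_id}"
        updated = r.model_copy(deep=True)
        updated.meta.split = assignment[key]
        out.append(updated)
    return out


def export_jsonl(records: list[InstructionRecord], path) -> None:
    """One JSON object per line (task/instruction/input/output/meta),
    UTF-8, keys sorted; importing the file reproduces the records."""
    lines = [json.dumps(r.model_dump(), sort_keys=True, ensure_ascii=False)
             for r in records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""),
                          encoding="utf-8")


def import_jsonl(path) -> list[InstructionRecord]:
    text = Path(path).read_text(encoding="utf-8")
    return [InstructionRecord.model_validate_json(line)
            for line in text.splitlines() if line.strip()]


def dataset_stats(records: list[InstructionRecord]) -> dict:
    """Record counts per task and split plus input/output token-length
    summaries (whitespace tokens)."""
    by_task: dict[str, int] = {}
    by_split: dict[str, int] = {}
    in_lens, out_lens = [], []
    for r in records:
        by_task[r.task] = by_task.get(r.task, 0) + 1
        split = r.meta.split or "unassigned"
        by_split[split] = by_split.get(split, 0) + 1
        in_lens.append(len(r.input.split()))
        out_lens.append(len(r.output.split()))
    def _summary(xs):
        if not xs:
            return {"n": 0}
        arr = np.asarray(xs)
        return {"n": len(xs), "mean": float(arr.mean()),
                "median": float(np.median(arr)), "max": int(arr.max())}
    return {"total": len(records), "by_task": by_task, "by_split": by_split,
            "input_tokens": _summary(in_lens),
            "output_tokens": _summary(out_lens)}
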