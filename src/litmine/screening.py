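"""Criterion-level study eligibility assessment and ranking.

Each candidate is assessed against every eligibility criterion of the
review; criterion labels YES / PARTIAL / UNCERTAIN / NO map to scores
1 / 0.5 / 0 / −1, and the final eligibility score is their arithmetic mean,
always in [−1, 1].  Candidates are ranked by descending final score (ties by
ascending study id), so the review's target studies should occupy the top
ranks when assessments are accurate.

The candidate pool mirrors how screening sets are built in practice: the
primary search hits come first, the pool is time-constrained to studies
published before the review, and any remaining slots (up to the pool size)
are filled with hits from single-element queries built from the other PICO
elements.
"""

from __future__ import annotations

import logging

from pydantic import BaseModel, Field

from .backends import GenerativeBackend, attach_context, get_prompt, render_prompt
from .boolean_query import Term, evaluate, or_, retrieve
from .corpus_model import (Criterion, LinkedCorpus, ReviewTopic, StudyRecord,
                           apply_time_constraint, tokenize)
from .errors import AggregationError, BackendOutputError, MappingError
from .parsing import parse_backend_json

logger = logging.getLogger(__name__)

LABEL_SCORES: dict[str, float] = {
    "YES": 1.0,
    "PARTIAL": 0.5,
    "UNCERTAIN": 0.0,
    "NO": -1.0,
}
# "Partially Yes" is the narrative name for the PARTIAL label.
_LABEL_ALIASES = {"PARTIALLY YES": "PARTIAL"}


def label_to_score(label: str) -> float:
    """Map an eligibility label to its score; unknown labels are an error,
    never silently coerced."""
    canon = _LABEL_ALIASES.get(label.strip().upper(), label.strip().upper())
    if canon not in LABEL_SCORES:
        raise MappingError(f"unknown eligibility label: {label!r}")
    return LABEL_SCORES[canon]


class CriterionAssessment(BaseModel):
    criterion: Criterion
    label: str
    rationale: str = ""

    @property
    def score(self) -> float:
        return label_to_score(self.label)


class EligibilityResult(BaseModel):
    study_id: str
    assessments: list[CriterionAssessment]
    final_score: float = Field(ge=-1.0, le=1.0)


def aggregate_score(assessments: list[CriterionAssessment]) -> float:
    """Arithmetic mean of criterion scores."""
    if not assessments:
        raise AggregationError("cannot aggregate an empty assessment list")
    return sum(a.score for a in assessments) / len(assessments)


def criteria_from_review(review: ReviewTopic) -> list[Criterion]:
    """The review's explicit criteria, or one derived criterion per
    non-empty PICO element when none are given."""
    if review.criteria:
        return review.criteria
    derived: list[Criterion] = []
    pico = review.pico
    for element, text, prefix in (
        ("P", pico.population, "Population"),
        ("I", pico.intervention, "Intervention"),
        ("C", pico.comparator, "Comparator"),
        ("O", pico.outcome, "Outcome"),
    ):
        if text.strip():
            derived.append(Criterion(element=element, text=f"{prefix}: {text}"))
    return derived


def _format_criteria(criteria: list[Criterion]) -> str:
    return "\n".join(f"{i + 1}. [{c.element}/{c.role}] {c.text}"
                     for i, c in enumerate(criteria))


def assess_study(criteria: list[Criterion], study: StudyRecord,
                 backend: GenerativeBackend, review_id: str | None = None,
                 seed: int = 0) -> EligibilityResult:
    """Assess one candidate against every criterion.

    Backend output is parsed as one (label, rationale) pair per criterion in
    order.  Missing or unparseable per-criterion answers degrade to
    UNCERTAIN (score 0) with a logged warning, so a noisy backend can never
    knock a study out of the ranking entirely.
    """
    if not criteria:
        raise AggregationError("assess_study requires at least one criterion")
    prompt = render_prompt(get_prompt("eligibility"), {
        "criteria": _format_criteria(criteria),
        "title": study.title, "abstract": study.abstract,
    })
    prompt = attach_context(prompt, task="eligibility", review_id=review_id,
                            study_id=study.study_id,
                            elements=[c.element for c in criteria])
    raw = backend.complete(prompt, seed=seed)
    try:
        payload = parse_backend_json(raw)
        items = payload["assessments"]
        if not isinstance(items, list):
            raise TypeError("assessments must be a list")
    except (BackendOutputError, KeyError, TypeError) as err:
        logger.warning("unparseable eligibility output for study %s (%s); "
                       "all criteria degraded to UNCERTAIN",
                       study.study_id, err)
        items = []

    assessments: list[CriterionAssessment] = []
    for i, criterion in enumerate(criteria):
        label, rationale = "UNCERTAIN", "unparsed"
        if i < len(items) and isinstance(items[i], dict):
            try:
                cand = str(items[i].get("label", ""))
                label_to_score(cand)  # validate
                label = cand.strip().upper()
                label = _LABEL_ALIASES.get(label, label)
                rationale = str(items[i].get("rationale", ""))
            except MappingError:
                logger.warning("criterion %d of study %s has unparseable "
                               "label %r; degraded to UNCERTAIN",
                               i, study.study_id, items[i].get("label"))
        assessments.append(CriterionAssessment(
            criterion=criterion, label=label, rationale=rationale))
    return EligibilityResult(study_id=study.study_id,
                             assessments=assessments,
                             final_score=aggregate_score(assessments))


_STOPWORDS = {"with", "and", "or", "of", "the", "in", "for", "a", "an", "to",
              "versus", "by"}


def _element_query(text: str):
    """A permissive single-element query: OR over the element's content
    words, used only to fill undersized candidate pools."""
    words = [w for w in tokenize(text) if w not in _STOPWORDS]
    if not words:
        return None
    return or_([Term(w) for w in dict.fromkeys(words)])


def build_candidate_pool(review: ReviewTopic, corpus: LinkedCorpus,
                         primary_hits: list[str],
                         pool_size: int = 2000) -> list[str]:
    """Time-constrained screening pool of at most ``pool_size`` candidates.

    Primary search hits come first (original order).  If the pool is short,
    hits from population-only, then intervention-only, then outcome-only
    queries are appended (deduplicated, time-constrained) until the pool is
    full or the queries are exhausted.  An undersized pool is returned as-is.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    primary = apply_time_constraint(
        review, [corpus.study(sid) for sid in primary_hits])
    pool: list[str] = [s.study_id for s in primary][:pool_size]
    seen = set(pool)
    if len(pool) < pool_size:
        for element_text in (review.pico.population, review.pico.intervention,
                             review.pico.outcome):
            query = _element_query(element_text)
            if query is None:
                continue
            fill = apply_time_constraint(
                review,
                [corpus.study(sid) for sid in retrieve(query, corpus,
                                                       limit=pool_size)])
            for s in fill:
                if s.study_id not in seen:
                    seen.add(s.study_id)
                    pool.append(s.study_id)
                    if len(pool) >= pool_size:
                        break
            if len(pool) >= pool_size:
                break
    if len(pool) < pool_size:
        logger.info("candidate pool for %s undersized: %d of %d",
                    review.review_id, len(pool), pool_size)
    return pool


def rank_candidates(results: list[EligibilityResult]) -> list[EligibilityResult]:
    """Descending final score; ties broken by ascending study id."""
    return sorted(results, key=lambda r: (-r.final_score, r.study_id))


SCORE_BANDS = ("predicted_false", "intermediate", "predicted_true")


def stratify_by_score(results: list[EligibilityResult]
                      ) -> dict[str, list[EligibilityResult]]:
    """Partition results into score bands: [−1, −0.5] predicted-ineligible,
    [0.75, 1] predicted-eligible, everything between is intermediate."""
    bands: dict[str, list[EligibilityResult]] = {b: [] for b in SCORE_BANDS}
    for r in results:
        if r.final_score <= -0.5:
            bands["predicted_false"].append(r)
        elif r.final_score >= 0.75:
            bands["predicted_true"].append(r)
        else:
            bands["intermediate"].append(r)
    return bands
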