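"""Search-query synthesis.

A review's search strategy is assembled from per-study keyword sets: for
each target study *n*, population terms ``P_n`` and intervention terms
``I_n`` (at most ten each) are combined as ``SP_n = AND(P_n)`` and
``SI_n = AND(I_n)``; the population clause is ``SP = SP_1 OR … OR SP_N``,
the intervention clause ``SI = SI_1 OR … OR SI_N``, and the final query is
``S = SP AND SI``.  Queries whose retrieval recall on the review's known
target studies falls below 0.2 are discarded as poorly generated; the
boundary is inclusive (recall exactly 0.2 is kept).

Generation from a PICO frame alone goes through a generative backend and an
ensemble mode that samples several queries with run-indexed seeds and
returns the deduplicated union of their search results.
"""

from __future__ import annotations

import logging
from typing import Optional

from pydantic import BaseModel, Field, field_validator

from .backends import GenerativeBackend, attach_context, get_prompt, render_prompt
from .boolean_query import And, BooleanQuery, Term, and_, evaluate, or_, retrieve
from .corpus_model import LinkedCorpus, PICOFrame, StudyRecord
from .errors import (AssemblyError, BackendOutputError, GenerationError,
                     UndefinedMetricError)
from .parsing import parse_backend_json

logger = logging.getLogger(__name__)

MAX_TERMS = 10  # per-study cap on extracted keywords per element


class TermSet(BaseModel):
    """Keyword sets extracted from one target study."""

    source_study_id: str
    population_terms: list[str] = Field(min_length=1, max_length=MAX_TERMS)
    intervention_terms: list[str] = Field(min_length=1, max_length=MAX_TERMS)

    @field_validator("population_terms", "intervention_terms")
    @classmethod
    def _non_empty_terms(cls, v: list[str]) -> list[str]:
        if any(not t or not t.strip() for t in v):
            raise ValueError("terms must be non-empty strings")
        return v


def _clean_terms(raw) -> list[str]:
    if not isinstance(raw, list):
        raise TypeError("expected a list of terms")
    seen: set[str] = set()
    out: list[str] = []
    for item in raw:
        if not isinstance(item, str):
            raise TypeError("terms must be strings")
        term = item.strip()
        if term and term not in seen:
            seen.add(term)
            out.append(term)
    return out[:MAX_TERMS]


def extract_terms(study: StudyRecord, backend: GenerativeBackend,
                  seed: int = 0) -> TermSet:
    """Ask the backend for population/intervention keywords of one study.

    Output lists are whitespace-trimmed, deduplicated (keeping first
    occurrence), and truncated to ten terms.
    """
    prompt = render_prompt(get_prompt("term_extraction"),
                           {"title": study.title, "abstract": study.abstract})
    prompt = attach_context(prompt, task="term_extraction",
                            study_id=study.study_id)
    raw = backend.complete(prompt, seed=seed)
    payload = parse_backend_json(raw)
    try:
        population = _clean_terms(payload["population"])
        intervention = _clean_terms(payload["intervention"])
        return TermSet(source_study_id=study.study_id,
                       population_terms=population,
                       intervention_terms=intervention)
    except (KeyError, TypeError, ValueError) as err:
        raise BackendOutputError(
            f"cannot parse term extraction output for study "
            f"{study.study_id}: {err}", raw_output=raw) from err


def assemble_query(termsets: list[TermSet],
                   inner_connective: str = "and") -> BooleanQuery:
    """Build ``S = (OR of per-study population groups) AND (OR of per-study
    intervention groups)``.

    ``inner_connective`` controls how terms combine *within* a study group;
    the default AND follows the construction above, OR gives a broader,
    more forgiving strategy.
    """
    if not termsets:
        raise AssemblyError("cannot assemble a query from zero term sets")
    if inner_connective not in ("and", "or"):
        raise AssemblyError(f"unknown inner connective {inner_connective!r}")
    inner = and_ if inner_connective == "and" else or_
    for ts in termsets:
        if not ts.population_terms or not ts.intervention_terms:
            raise AssemblyError(
                f"term set for study {ts.source_study_id} has an empty list")
    sp = or_([inner([Term(t) for t in ts.population_terms]) for ts in termsets])
    si = or_([inner([Term(t) for t in ts.intervention_terms]) for ts in termsets])
    return And((sp, si))


class FilterDecision(BaseModel):
    keep: bool
    recall: float


def filter_by_recall(query: BooleanQuery, corpus: LinkedCorpus,
                     truth: set[str] | frozenset[str],
                     threshold: float = 0.2) -> FilterDecision:
    """Measure retrieval recall of ``query`` on ``truth`` and keep it iff
    recall >= threshold (queries *below* the threshold are dropped)."""
    if not truth:
        raise UndefinedMetricError("recall is undefined for an empty truth set")
    hits = evaluate(query, corpus)
    recall = len(hits & set(truth)) / len(truth)
    return FilterDecision(keep=recall >= threshold, recall=recall)


def generate_query(pico: PICOFrame, backend: GenerativeBackend,
                   seed: int = 0,
                   review_id: Optional[str] = None) -> BooleanQuery:
    """Generate a boolean query from a PICO frame via the backend.

    The backend's keyword groups (one population+intervention pair per
    anticipated study profile) are assembled exactly like per-study term
    sets.  A group missing either keyword list is a generation error.
    """
    prompt = render_prompt(get_prompt("query_generation"), {
        "population": pico.population, "intervention": pico.intervention,
        "comparator": pico.comparator, "outcome": pico.outcome,
    })
    prompt = attach_context(prompt, task="query_generation",
                            review_id=review_id)
    raw = backend.complete(prompt, seed=seed)
    try:
        payload = parse_backend_json(raw)
    except BackendOutputError as err:
        raise GenerationError(str(err), raw_output=raw) from err
    groups = payload.get("groups") if isinstance(payload, dict) else None
    if not isinstance(groups, list) or not groups:
        raise GenerationError("backend emitted no keyword groups",
                              raw_output=raw)
    termsets: list[TermSet] = []
    for i, group in enumerate(groups):
        try:
            population = _clean_terms(group["population"])
            intervention = _clean_terms(group["intervention"])
            termsets.append(TermSet(source_study_id=f"group{i}",
                                    population_terms=population,
                                    intervention_terms=intervention))
        except (KeyError, TypeError, ValueError) as err:
            raise GenerationError(
                f"keyword group {i} is incomplete: {err}",
                raw_output=raw) from err
    return assemble_query(termsets)


def ensemble_generate(pico: PICOFrame, backend: GenerativeBackend,
                      corpus: LinkedCorpus, limit: int,
                      n_runs: int = 10, seed: int = 0,
                      review_id: Optional[str] = None) -> list[str]:
    """Sample ``n_runs`` queries with run-indexed seeds, retrieve each, and
    return the concatenated, first-occurrence-deduplicated hit list.

    Failed runs are logged and skipped; if every run fails the ensemble is
    a generation error.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    merged: list[str] = []
    seen: set[str] = set()
    n_ok = 0
    for run in range(n_runs):
        try:
            query = generate_query(pico, backend, seed=seed + run,
                                   review_id=review_id)
        except GenerationError as err:
            logger.warning("ensemble run %d failed: %s", run, err)
            continue
        n_ok += 1
        for sid in retrieve(query, corpus, limit):
            if sid not in seen:
                seen.add(sid)
                merged.append(sid)
    if n_ok == 0:
        raise GenerationError("all ensemble runs failed to generate a query")
    return merged
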