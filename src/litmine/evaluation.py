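"""Evaluation metrics for search, screening, and extraction.

Search and screening quality is recall@K: the fraction of a review's target
studies appearing in the top K of a ranked list.  The strict variant sets K
to the number of target studies, so a perfect score requires every target
study to outrank every distractor.  Extraction quality is field accuracy:
numeric fields require exact value equality after lenient parsing, text
fields use embedding cosine similarity with an inclusive 0.75 threshold,
and list-valued fields are scored element-wise, aligned by key (arm label,
group id, result title) where one exists and by position otherwise.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel

from .backends import EmbeddingBackend, HashedNgramEmbedder
from .errors import UndefinedMetricError
from .extraction import (ArmDesignResult, CharacteristicsResult,
                         DEFAULT_CHARACTERISTICS_FIELDS, FieldSpec,
                         ParticipantStatsResult, TrialResultResult)
from .parsing import parse_number

logger = logging.getLogger(__name__)


class RecallReport(BaseModel):
    review_id: str
    k: int
    recall: float
    n_truth: int


# ---------------------------------------------------------------------------
# Recall
# ---------------------------------------------------------------------------

def recall_at_k(ranked: Sequence[str], truth: set[str] | frozenset[str],
                k: int) -> float:
    """|top-k(ranked) ∩ truth| / |truth|; if fewer than k results exist the
    whole list is used."""
    if not truth:
        raise UndefinedMetricError("recall is undefined for an empty truth set")
    if k < 1:
        raise ValueError("k must be >= 1")
    return len(set(ranked[:k]) & set(truth)) / len(truth)


def recall_at_truth_size(ranked: Sequence[str],
                         truth: set[str] | frozenset[str]) -> float:
    """The strict variant: recall@K with K = |truth|."""
    if not truth:
        raise UndefinedMetricError("recall is undefined for an empty truth set")
    return recall_at_k(ranked, truth, len(truth))


# ---------------------------------------------------------------------------
# Field matching
# ---------------------------------------------------------------------------

def exact_numeric_match(pred, truth: float) -> bool:
    """Exact decimal equality after normalising the prediction (thousands
    separators, percent signs, and unit words stripped).  Unparseable
    predictions score incorrect rather than raising."""
    if truth is None or not math.isfinite(float(truth)):
        raise ValueError("truth must be a finite number")
    value = parse_number(pred)
    if value is None:
        logger.warning("numeric prediction %r could not be parsed; "
                       "scored incorrect", pred)
        return False
    return value == float(truth)


def text_similarity(pred: str, truth: str,
                    embedder: Optional[EmbeddingBackend] = None) -> float:
    """Cosine similarity between embedded texts (0.0 for a zero vector)."""
    embedder = embedder or HashedNgramEmbedder()
    a, b = embedder.embed(pred), embedder.embed(truth)
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        logger.warning("zero-vector embedding while comparing %r and %r",
                       pred, truth)
        return 0.0
    # guard against floating overshoot beyond ±1
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def soft_text_match(pred: str, truth: str,
                    embedder: Optional[EmbeddingBackend] = None,
                    threshold: float = 0.75) -> bool:
    """Cosine similarity at or above the threshold counts as correct."""
    if not pred or not truth:
        raise ValueError("soft_text_match requires non-empty texts")
    return text_similarity(pred, truth, embedder) >= threshold


# ---------------------------------------------------------------------------
# Field accuracy
# ---------------------------------------------------------------------------

class FieldAccuracyReport(BaseModel):
    numeric_correct: int = 0
    numeric_total: int = 0
    text_correct: int = 0
    text_total: int = 0

    @property
    def numeric_accuracy(self) -> Optional[float]:
        return (self.numeric_correct / self.numeric_total
                if self.numeric_total else None)

    @property
    def text_accuracy(self) -> Optional[float]:
        return self.text_correct / self.text_total if self.text_total else None

    @property
    def overall(self) -> float:
        total = self.numeric_total + self.text_total
        if total == 0:
            raise UndefinedMetricError("no fields were scored")
        return (self.numeric_correct + self.text_correct) / total

    def merged(self, other: "FieldAccuracyReport") -> "FieldAccuracyReport":
        return FieldAccuracyReport(
            numeric_correct=self.numeric_correct + other.numeric_correct,
            numeric_total=self.numeric_total + other.numeric_total,
            text_correct=self.text_correct + other.text_correct,
            text_total=self.text_total + other.text_total)


class _Scorer:
    def __init__(self, embedder: Optional[EmbeddingBackend],
                 threshold: float):
        self.embedder = embedder or HashedNgramEmbedder()
        self.threshold = threshold
        self.report = FieldAccuracyReport()

    def number(self, pred, truth) -> None:
        self.report.numeric_total += 1
        if truth is None:
            return
        if pred is not None and exact_numeric_match(pred, truth):
            self.report.numeric_correct += 1

    def text(self, pred, truth, exact: bool = False) -> None:
        self.report.text_total += 1
        if pred is None or truth is None:
            return
        pred_s, truth_s = str(pred), str(truth)
        if pred_s == truth_s:
            self.report.text_correct += 1
            return
        if exact or not pred_s or not truth_s:
            return
        if soft_text_match(pred_s, truth_s, self.embedder, self.threshold):
            self.report.text_correct += 1

    def text_list(self, pred, truth: list[str]) -> None:
        pred_list = pred if isinstance(pred, list) else None
        for i, t in enumerate(truth):
            p = pred_list[i] if pred_list is not None and i < len(pred_list) else None
            self.text(p, t)


def _score_characteristics(scorer: _Scorer, pred: CharacteristicsResult,
                           truth: CharacteristicsResult,
                           fields: list[FieldSpec]) -> None:
    for spec in fields:
        t = truth.values.get(spec.name)
        p = pred.values.get(spec.name)
        if spec.value_kind == "number":
            scorer.number(p, t)
        elif isinstance(t, list):
            scorer.text_list(p, t)
        else:
            scorer.text(p, t, exact=(spec.value_kind == "categorical"))


def _score_arms(scorer: _Scorer, pred: ArmDesignResult,
                truth: ArmDesignResult) -> None:
    by_label = {a.label: a for a in pred.arms}
    for t in truth.arms:
        p = by_label.get(t.label)
        scorer.text(p.label if p else None, t.label)
        scorer.text(p.arm_type if p else None, t.arm_type, exact=True)
        scorer.text(p.description if p else None, t.description)
        scorer.text_list(p.intervention_names if p else None,
                         t.intervention_names)


def _score_participants(scorer: _Scorer, pred: ParticipantStatsResult,
                        truth: ParticipantStatsResult) -> None:
    by_group = {r.group_id: r for r in pred.results}
    for t in truth.results:
        p = by_group.get(t.group_id)
        scorer.number(p.value if p else None, t.value)
        if t.notes:
            scorer.text(p.notes if p else None, t.notes)


def _score_trial_results(scorer: _Scorer, pred: TrialResultResult,
                         truth: TrialResultResult) -> None:
    titles = [t.title for t in truth.results]
    use_titles = len(set(titles)) == len(titles) and all(titles)
    by_title = {r.title: r for r in pred.results}
    for i, t in enumerate(truth.results):
        if use_titles:
            p = by_title.get(t.title)
        else:
            p = pred.results[i] if i < len(pred.results) else None
        scorer.number(p.value if p else None, t.value)
        if t.title:
            scorer.text(p.title if p else None, t.title)


def field_accuracy(results: list[tuple], schema,
                   embedder: Optional[EmbeddingBackend] = None,
                   threshold: float = 0.75) -> FieldAccuracyReport:
    """Score (prediction, truth) record pairs for one extraction task.

    ``schema`` is a task name (``arm_design``, ``participant_stats``,
    ``trial_results``, ``characteristics``) or a list of
    :class:`FieldSpec` for a custom characteristics schema.  Accuracies are
    correct/total per value kind, with totals driven by the truth records.
    """
    if not results:
        raise UndefinedMetricError("field accuracy is undefined for an "
                                   "empty result list")
    if isinstance(schema, list):
        task, fields = "characteristics", schema
    else:
        task, fields = schema, DEFAULT_CHARACTERISTICS_FIELDS
    scorer = _Scorer(embedder, threshold)
    for pred, truth in results:
        if type(pred) is not type(truth):
            raise UndefinedMetricError(
                f"schema mismatch: prediction {type(pred).__name__} vs "
                f"truth {type(truth).__name__}")
        if task == "characteristics":
            _score_characteristics(scorer, pred, truth, fields)
        elif task == "arm_design":
            _score_arms(scorer, pred, truth)
        elif task == "participant_stats":
            _score_participants(scorer, pred, truth)
        elif task == "trial_results":
            _score_trial_results(scorer, pred, truth)
        else:
            raise ValueError(f"unknown task schema {schema!r}")
    return scorer.report


# ---------------------------------------------------------------------------
# Difficulty binning
# ---------------------------------------------------------------------------

class BinSummary(BaseModel):
    lo: int
    hi: int
    n: int
    mean_recall: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def bin_by_truth_count(reports: list[RecallReport],
                       bin_width: int = 5,
                       min_ci_n: int = 10) -> dict[str, BinSummary]:
    """Group per-review recalls by the number of target studies into
    ``[0-5), [5-10), …`` bins, reporting the mean with a normal 95%
    confidence interval (omitted for bins with fewer than ``min_ci_n``
    reviews)."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    groups: dict[int, list[float]] = {}
    for r in reports:
        groups.setdefault(r.n_truth // bin_width, []).append(r.recall)
    out: dict[str, BinSummary] = {}
    for idx in sorted(groups):
        vals = np.asarray(groups[idx])
        lo, hi = idx * bin_width, (idx + 1) * bin_width
        summary = BinSummary(lo=lo, hi=hi, n=len(vals),
                             mean_recall=float(vals.mean()))
        if len(vals) >= min_ci_n:
            half = 1.96 * float(vals.std(ddof=1)) / math.sqrt(len(vals))
            summary.ci_low = summary.mean_recall - half
            summary.ci_high = summary.mean_recall + half
        out[f"[{lo}-{hi})"] = summary
    return out
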