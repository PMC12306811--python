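"""Domain types and the synthetic linked-corpus generator.

The corpus links three kinds of objects the way evidence-synthesis data
sources do in practice: systematic-review topics (a research question framed
as PICO plus eligibility criteria), publication citations, and clinical-trial
registry records attached to publications through NCT identifiers.  The
ground truth — which studies each review included, which keyword sets were
planted in each included study, and the structured registry data embedded in
pseudo-full-text — travels with the corpus so that every downstream stage
(query synthesis, screening, extraction) can be verified offline against a
deterministic oracle.

The generator is a pure function of its configuration, including the seed:
identical configurations produce byte-identical corpora.
"""

from __future__ import annotations

import datetime
import json
import logging
import re
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, PrivateAttr, model_validator

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> tuple[str, ...]:
    """Lowercase alphanumeric tokens of *text* (punctuation discarded)."""
    return tuple(_TOKEN_RE.findall(text.lower()))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class PICOFrame(BaseModel):
    """A research question structured as Population / Intervention /
    Comparator / Outcome.  Comparator and outcome may be empty; population
    and intervention must be non-empty for any review used in query
    synthesis."""

    population: str
    intervention: str
    comparator: str = ""
    outcome: str = ""


class Criterion(BaseModel):
    """A single eligibility criterion, categorised under one PICO element."""

    element: Literal["P", "I", "C", "O"]
    text: str = Field(min_length=1)
    role: Literal["inclusion", "exclusion"] = "inclusion"


class ReviewTopic(BaseModel):
    """A systematic-review topic: the unit around which searching,
    screening, and instruction building are organised."""

    review_id: str
    title: str
    abstract: str = ""
    pico: PICOFrame
    criteria: list[Criterion] = Field(default_factory=list)
    topic_area: str = "general"
    pub_date: datetime.date


class ArmRecord(BaseModel):
    """One intervention arm of a trial: unique label, arm type (for example
    ``EXPERIMENTAL``), free-text description, and the interventions given."""

    label: str = Field(min_length=1)
    arm_type: str = ""
    description: str = ""
    intervention_names: list[str] = Field(default_factory=list)


class GroupSpec(BaseModel):
    """A participant group referenced by baseline measures: registry-style
    group id (``BG000`` …), optional unit and size, and a definition."""

    group_id: str
    unit: str = ""
    value: Optional[float] = None
    definition: str = ""


class ParticipantValue(BaseModel):
    group_id: str
    value: float
    notes: str = ""


class ParticipantMeasureTruth(BaseModel):
    """Ground truth for one baseline participant measure (e.g. mean age),
    with per-group values."""

    measure_definition: str
    parameter_type: str
    unit: str
    groups: list[GroupSpec]
    results: list[ParticipantValue]


class TrialResultValue(BaseModel):
    value: float
    title: str = ""


class TrialResultTruth(BaseModel):
    """Ground truth for one reported trial outcome."""

    outcome_definition: str
    group_definition: str
    parameter_type: str
    unit: str
    timeframe: str
    denominator_unit: str = ""
    denominator_value: Optional[float] = None
    results: list[TrialResultValue]

    @model_validator(mode="after")
    def _nonneg_denominator(self) -> "TrialResultTruth":
        if self.denominator_value is not None and self.denominator_value < 0:
            raise ValueError("denominator_value must be >= 0")
        return self


class RegistryData(BaseModel):
    """Structured registry-style trial record: the extraction ground truth."""

    conditions: list[str] = Field(default_factory=list)
    interventions: list[str] = Field(default_factory=list)
    enrollment: int = Field(ge=0, default=0)
    study_type: str = ""
    arms: list[ArmRecord] = Field(default_factory=list)
    participant_measures: list[ParticipantMeasureTruth] = Field(default_factory=list)
    outcome_results: list[TrialResultTruth] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_arm_labels(self) -> "RegistryData":
        labels = [a.label for a in self.arms]
        if len(labels) != len(set(labels)):
            raise ValueError("arm labels must be unique within a record")
        return self


class StudyRecord(BaseModel):
    """A candidate study: either a publication citation (title/abstract,
    optionally full text and table text, optionally an NCT link) or a
    trial-registry record carrying structured ground truth."""

    study_id: str
    kind: Literal["publication", "trial_registry"] = "publication"
    title: str = ""
    abstract: str = ""
    full_text: Optional[str] = None
    table_text: Optional[list[str]] = None
    pub_date: Optional[datetime.date] = None
    nct_link: Optional[str] = None
    registry_truth: Optional[RegistryData] = None

    def searchable_text(self) -> str:
        return f"{self.title} {self.abstract}"


class PlantedTerms(BaseModel):
    """The keyword sets the generator embedded verbatim into one included
    study; the oracle backend answers term-extraction prompts from these."""

    population: list[str]
    intervention: list[str]


class LinkedCorpus(BaseModel):
    """Reviews, studies, and the inclusion ground truth linking them.

    ``inclusion_truth`` maps each review id to the ids of its included
    studies (the review's N target studies).  ``planted_terms`` and
    ``element_terms`` carry the generator's keyword ground truth used by the
    oracle backends; corpora built from real data may leave them empty.
    """

    reviews: list[ReviewTopic]
    studies: list[StudyRecord]
    inclusion_truth: dict[str, list[str]]
    planted_terms: dict[str, PlantedTerms] = Field(default_factory=dict)
    element_terms: dict[str, dict[str, list[str]]] = Field(default_factory=dict)

    _by_study: dict[str, StudyRecord] = PrivateAttr(default=None)
    _by_review: dict[str, ReviewTopic] = PrivateAttr(default=None)
    _tokens: dict[str, tuple[str, ...]] = PrivateAttr(default=None)

    @model_validator(mode="after")
    def _check_truth_ids(self) -> "LinkedCorpus":
        known = {s.study_id for s in self.studies}
        for rid, ids in self.inclusion_truth.items():
            missing = set(ids) - known
            if missing:
                raise ValueError(
                    f"inclusion_truth[{rid}] references unknown study ids: "
                    f"{sorted(missing)}"
                )
        return self

    # -- lookup helpers ----------------------------------------------------
    def study(self, study_id: str) -> StudyRecord:
        if self._by_study is None:
            self._by_study = {s.study_id: s for s in self.studies}
        return self._by_study[study_id]

    def review(self, review_id: str) -> ReviewTopic:
        if self._by_review is None:
            self._by_review = {r.review_id: r for r in self.reviews}
        return self._by_review[review_id]

    def truth(self, review_id: str) -> frozenset[str]:
        return frozenset(self.inclusion_truth.get(review_id, ()))

    def token_index(self) -> dict[str, tuple[str, ...]]:
        """Cached study-id → title+abstract token sequence map."""
        if self._tokens is None:
            self._tokens = {
                s.study_id: tokenize(s.searchable_text()) for s in self.studies
            }
        return self._tokens

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return self.model_dump_json(indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "LinkedCorpus":
        return cls.model_validate_json(text)

    @classmethod
    def load(cls, path: str | Path) -> "LinkedCorpus":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def corpus_json_schema() -> dict:
    """JSON schema for the corpus interchange document."""
    return LinkedCorpus.model_json_schema()


# ---------------------------------------------------------------------------
# Synthetic corpus generation
# ---------------------------------------------------------------------------

class SyntheticConfig(BaseModel):
    """Configuration for :func:`generate_corpus`.

    ``overlap_rate`` controls how much of a review's planted vocabulary leaks
    into its distractors: each planted term is embedded into each distractor
    independently with this probability, so term overlap is Binomial.
    ``post_review_fraction`` of distractors are dated after the review, to
    exercise the publication-date constraint.
    """

    n_reviews: int
    included_per_review: int
    distractors_per_review: int
    vocab_size: int = 400
    overlap_rate: float = 0.1
    seed: int = 0
    post_review_fraction: float = 0.1
    empty_co_rate: float = 0.0
    emit_registry_records: bool = True

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for name in ("n_reviews", "included_per_review", "distractors_per_review",
                     "vocab_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("overlap_rate", "post_review_fraction", "empty_co_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.vocab_size < 2 * self.n_reviews * (self.included_per_review + 1):
            raise ConfigurationError(
                "vocab_size too small: need two pseudo-terms per included "
                "study plus two per review "
                "(vocab_size >= 2 * n_reviews * (included_per_review + 1))"
            )
        return self


# Real clinical vocabulary so token matching exercises realistic multi-word
# phrases; pseudo-terms (pronounceable nonsense) make planted keywords
# unambiguous within a corpus.
_CONDITIONS = [
    "atrial fibrillation", "type 2 diabetes", "major depressive disorder",
    "chronic obstructive pulmonary disease", "rheumatoid arthritis",
    "heart failure", "asthma", "hypertension", "ischemic stroke",
    "chronic kidney disease", "migraine", "psoriasis", "osteoporosis",
    "epilepsy", "ulcerative colitis", "multiple sclerosis", "glaucoma",
    "hepatitis c", "low back pain", "obstructive sleep apnea",
    "parkinson disease", "alzheimer disease", "sepsis", "melanoma",
]
_INTERVENTIONS = [
    "warfarin", "metformin", "sertraline", "tiotropium", "methotrexate",
    "bisoprolol", "budesonide", "amlodipine", "alteplase", "dapagliflozin",
    "topiramate", "ustekinumab", "alendronate", "levetiracetam",
    "mesalamine", "ocrelizumab", "latanoprost", "sofosbuvir",
    "duloxetine", "continuous positive airway pressure",
    "levodopa", "donepezil", "vancomycin", "pembrolizumab",
]
_COMPARATORS = ["placebo", "usual care", "sham procedure", "active control"]
_OUTCOMES = [
    "all cause mortality", "symptom severity score", "hospital readmission",
    "quality of life score", "relapse rate", "pain intensity score",
]
_TOPIC_AREAS = [
    "cardiology", "endocrinology", "psychiatry", "pulmonology",
    "rheumatology", "neurology", "dermatology", "nephrology",
    "gastroenterology", "ophthalmology",
]
# Generic prose used in every record; deliberately disjoint from the planted
# vocabulary above.  "patients" appears in both review population framing and
# distractor prose so element-wise fill queries have something to retrieve.
_FILLER_SENTENCES = [
    "We conducted a multicenter study of adult patients recruited from outpatient clinics.",
    "Baseline demographics were balanced between the study groups of patients.",
    "Follow up visits were scheduled at regular intervals for all patients.",
    "The primary analysis followed the intention to treat principle.",
    "Adverse events were recorded throughout the observation period.",
    "Secondary analyses were prespecified in the protocol.",
    "Eligible patients provided written informed consent before enrollment.",
    "Data were collected using standardized case report forms.",
]

_SYLLABLES = [c + v for c in "bdfgklmnprstvz" for v in "aeiou"]


def _pseudo_vocab(rng: np.random.Generator, size: int) -> list[str]:
    """Deterministic pool of unique pronounceable pseudo-terms."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < size:
        n_syll = int(rng.integers(3, 5))
        word = "".join(rng.choice(_SYLLABLES) for _ in range(n_syll))
        if word not in seen:
            seen.add(word)
            out.append(word)
    return out


def _rand_date(rng: np.random.Generator, lo: datetime.date,
               hi: datetime.date) -> datetime.date:
    span = (hi - lo).days
    return lo + datetime.timedelta(days=int(rng.integers(0, max(span, 1))))


def _fmt(x: float) -> str:
    """Fixed one-decimal rendering used when embedding numbers in text."""
    return f"{x:.1f}"


def registry_value_strings(truth: RegistryData) -> list[str]:
    """Every registry ground-truth value as the string that must appear
    verbatim in an included publication's full text or tables."""
    out: list[str] = []
    out.extend(truth.conditions)
    out.extend(truth.interventions)
    out.append(str(truth.enrollment))
    out.append(truth.study_type)
    for arm in truth.arms:
        out.extend([arm.label, arm.arm_type, arm.description])
        out.extend(arm.intervention_names)
    for pm in truth.participant_measures:
        out.extend([pm.measure_definition, pm.parameter_type, pm.unit])
        for g in pm.groups:
            out.extend([g.group_id, g.definition])
            if g.value is not None:
                out.append(str(int(g.value)))
        for r in pm.results:
            out.append(_fmt(r.value))
    for tr in truth.outcome_results:
        out.extend([tr.outcome_definition, tr.group_definition,
                    tr.parameter_type, tr.unit, tr.timeframe,
                    tr.denominator_unit])
        if tr.denominator_value is not None:
            out.append(str(int(tr.denominator_value)))
        for r in tr.results:
            out.extend([_fmt(r.value), r.title])
    return [s for s in out if s]


def _make_registry_truth(rng: np.random.Generator, cond: str, interv: str,
                         comp: str, outcome: str) -> RegistryData:
    enrollment = int(rng.integers(60, 480))
    n_treat = enrollment // 2
    n_ctrl = enrollment - n_treat
    arms = [
        ArmRecord(label=f"{interv} arm", arm_type="EXPERIMENTAL",
                  description=f"Participants receiving {interv}",
                  intervention_names=[interv]),
        ArmRecord(label=f"{comp} arm", arm_type="COMPARATOR",
                  description=f"Participants receiving {comp}",
                  intervention_names=[comp]),
    ]
    age_t = round(float(rng.uniform(45, 75)), 1)
    age_c = round(float(rng.uniform(45, 75)), 1)
    measure = ParticipantMeasureTruth(
        measure_definition="Age of participants",
        parameter_type="MEAN", unit="years",
        groups=[
            GroupSpec(group_id="BG000", unit="Participants", value=float(n_treat),
                      definition=f"{interv} group"),
            GroupSpec(group_id="BG001", unit="Participants", value=float(n_ctrl),
                      definition=f"{comp} group"),
        ],
        results=[
            ParticipantValue(group_id="BG000", value=age_t, notes=""),
            ParticipantValue(group_id="BG001", value=age_c, notes=""),
        ],
    )
    out_t = round(float(rng.uniform(5, 60)), 1)
    out_c = round(float(rng.uniform(5, 60)), 1)
    result = TrialResultTruth(
        outcome_definition=f"Change in {outcome}",
        group_definition="All randomized participants",
        parameter_type="MEAN", unit="points", timeframe="12 weeks",
        denominator_unit="Participants", denominator_value=float(enrollment),
        results=[
            TrialResultValue(value=out_t, title=f"{interv} arm"),
            TrialResultValue(value=out_c, title=f"{comp} arm"),
        ],
    )
    return RegistryData(
        conditions=[cond], interventions=[interv, comp],
        enrollment=enrollment, study_type="INTERVENTIONAL",
        arms=arms, participant_measures=[measure], outcome_results=[result],
    )


def _registry_full_text(truth: RegistryData, cond: str) -> tuple[str, list[str]]:
    """Pseudo-full-text sections and table blocks embedding every registry
    value verbatim (the extraction round-trip precondition)."""
    arms_sent = " ".join(
        f"{a.label} ({a.arm_type}): {a.description}; interventions: "
        f"{', '.join(a.intervention_names)}." for a in truth.arms
    )
    full_text = (
        f"Methods. This {truth.study_type} study enrolled {truth.enrollment} "
        f"patients with {', '.join(truth.conditions)}. "
        f"Study interventions were {', '.join(truth.interventions)}. "
        f"{arms_sent} "
        "Results. Baseline measures and outcomes are reported in the tables."
    )
    tables: list[str] = []
    for pm in truth.participant_measures:
        cells = " ".join(
            f"{g.group_id} {g.definition} (n={int(g.value)}): "
            f"{_fmt(next(r.value for r in pm.results if r.group_id == g.group_id))}."
            for g in pm.groups
        )
        tables.append(
            f"Table. Baseline measure: {pm.measure_definition}. "
            f"Parameter: {pm.parameter_type}. Unit: {pm.unit}. {cells}"
        )
    for tr in truth.outcome_results:
        cells = " ".join(f"{r.title}: {_fmt(r.value)}." for r in tr.results)
        tables.append(
            f"Table. Outcome: {tr.outcome_definition}. "
            f"Groups: {tr.group_definition}. Parameter: {tr.parameter_type}. "
            f"Unit: {tr.unit}. Timeframe: {tr.timeframe}. "
            f"Denominator: {int(tr.denominator_value)} {tr.denominator_unit}. {cells}"
        )
    return full_text, tables


def generate_corpus(config: SyntheticConfig) -> LinkedCorpus:
    """Generate a linked corpus with known inclusion/keyword/registry truth.

    Each review plants one real condition term, one real intervention term,
    and two unique pseudo-terms per included study; the included study's
    title and abstract contain all of its planted terms verbatim.
    Distractors are generic trial prose sharing a Binomial(overlap_rate)
    subset of the review's planted vocabulary.  Included publications embed
    their registry ground truth verbatim in pseudo-full-text and tables, and
    always predate the review.
    """
    rng = np.random.default_rng(config.seed)
    pseudo = _pseudo_vocab(rng, config.vocab_size)
    pseudo_iter = iter(pseudo)

    n_pubs = config.n_reviews * (config.included_per_review
                                 + config.distractors_per_review)
    # Random, non-repeating PMID-like ids so ranking tie-breaks are not
    # correlated with inclusion status.
    pmids = rng.choice(np.arange(10_000_000, 10_000_000 + 4 * n_pubs),
                       size=n_pubs, replace=False)
    pmid_iter = iter(str(int(p)) for p in pmids)
    nct_counter = iter(range(10_000_000, 99_999_999))

    reviews: list[ReviewTopic] = []
    studies: list[StudyRecord] = []
    inclusion: dict[str, list[str]] = {}
    planted: dict[str, PlantedTerms] = {}
    element_terms: dict[str, dict[str, list[str]]] = {}

    for i in range(config.n_reviews):
        rid = f"REV{i:04d}"
        cond = _CONDITIONS[i % len(_CONDITIONS)]
        interv = _INTERVENTIONS[i % len(_INTERVENTIONS)]
        # comparator/outcome phrases get a review-unique pseudo qualifier so
        # element terms never collide across reviews even when the real
        # vocabulary cycles
        comp = f"{_COMPARATORS[i % len(_COMPARATORS)]} {next(pseudo_iter)}"
        outcome = f"{_OUTCOMES[i % len(_OUTCOMES)]} {next(pseudo_iter)}"
        drop_co = rng.random() < config.empty_co_rate
        review_date = _rand_date(rng, datetime.date(2017, 1, 1),
                                 datetime.date(2022, 12, 31))
        pico = PICOFrame(
            population=f"patients with {cond}",
            intervention=interv,
            comparator="" if drop_co else comp,
            outcome="" if drop_co else outcome,
        )
        criteria = [Criterion(element="P", text=f"Population: patients with {cond}"),
                    Criterion(element="I", text=f"Intervention: {interv}")]
        elems = {"P": [cond], "I": [interv]}
        if not drop_co:
            criteria.append(Criterion(element="C", text=f"Comparator: {comp}"))
            criteria.append(Criterion(element="O", text=f"Outcome: {outcome}"))
            elems["C"] = [comp]
            elems["O"] = [outcome]
        reviews.append(ReviewTopic(
            review_id=rid,
            title=f"{interv} for {cond}: a systematic review",
            abstract=(f"We review trials of {interv} versus {comp} in patients "
                      f"with {cond}, assessing {outcome}."),
            pico=pico, criteria=criteria,
            topic_area=_TOPIC_AREAS[i % len(_TOPIC_AREAS)],
            pub_date=review_date,
        ))
        element_terms[rid] = elems

        review_term_pool: list[str] = [cond, interv, comp, outcome]
        included_ids: list[str] = []
        for _ in range(config.included_per_review):
            sid = next(pmid_iter)
            pop_pseudo = next(pseudo_iter)
            int_pseudo = next(pseudo_iter)
            review_term_pool.extend([pop_pseudo, int_pseudo])
            p_terms = [cond, pop_pseudo]
            i_terms = [interv, int_pseudo]
            pub_date = _rand_date(rng, review_date - datetime.timedelta(days=3650),
                                  review_date - datetime.timedelta(days=30))
            truth_data = _make_registry_truth(rng, cond, interv, comp, outcome)
            full_text, tables = _registry_full_text(truth_data, cond)
            nct = f"NCT{next(nct_counter):08d}"
            filler = rng.choice(_FILLER_SENTENCES, size=2, replace=False)
            studies.append(StudyRecord(
                study_id=sid, kind="publication",
                title=(f"{interv} {int_pseudo} versus {comp} in patients with "
                       f"{cond} {pop_pseudo}: a randomized trial"),
                abstract=(f"Background: patients with {cond} {pop_pseudo} have "
                          f"limited options. We evaluated {interv} {int_pseudo} "
                          f"against {comp}, measuring {outcome}. {filler[0]} "
                          f"{filler[1]}"),
                full_text=full_text, table_text=tables,
                pub_date=pub_date, nct_link=nct, registry_truth=truth_data,
            ))
            planted[sid] = PlantedTerms(population=p_terms, intervention=i_terms)
            included_ids.append(sid)
            if config.emit_registry_records:
                studies.append(StudyRecord(
                    study_id=nct, kind="trial_registry",
                    title=f"Registry record {nct}",
                    abstract=("Structured registry entry describing study "
                              "design, groups, and reported results."),
                    pub_date=pub_date, registry_truth=truth_data,
                ))
        inclusion[rid] = sorted(included_ids)

        n_post = int(round(config.post_review_fraction
                           * config.distractors_per_review))
        for d in range(config.distractors_per_review):
            sid = next(pmid_iter)
            if d < n_post:
                pub_date = _rand_date(rng, review_date,
                                      review_date + datetime.timedelta(days=720))
            else:
                pub_date = _rand_date(rng,
                                      review_date - datetime.timedelta(days=3650),
                                      review_date - datetime.timedelta(days=30))
            mask = rng.random(len(review_term_pool)) < config.overlap_rate
            shared = [t for t, m in zip(review_term_pool, mask) if m]
            filler = rng.choice(_FILLER_SENTENCES, size=3, replace=False)
            shared_sent = (f" This report also discusses {', '.join(shared)}."
                           if shared else "")
            studies.append(StudyRecord(
                study_id=sid, kind="publication",
                title="An observational cohort study of routine clinical care",
                abstract=f"{filler[0]} {filler[1]} {filler[2]}{shared_sent}",
                pub_date=pub_date,
            ))

    return LinkedCorpus(
        reviews=reviews, studies=studies, inclusion_truth=inclusion,
        planted_terms=planted, element_terms=element_terms,
    )


def apply_time_constraint(review: ReviewTopic,
                          candidates: list[StudyRecord]) -> list[StudyRecord]:
    """Keep candidates published strictly before the review, preserving
    order.  Records lacking a publication date are skipped with a warning."""
    kept: list[StudyRecord] = []
    for c in candidates:
        if c.pub_date is None:
            logger.warning("study %s has no pub_date; excluded from the "
                           "time-constrained pool", c.study_id)
            continue
        if c.pub_date < review.pub_date:
            kept.append(c)
    return kept
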