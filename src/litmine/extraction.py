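"""Structured data extraction from clinical-trial publications.

Four tasks mirror what a reviewer tabulates from a trial paper:

* **characteristics** — predefined study-level fields (conditions,
  interventions, enrollment, study type by default; user-extensible via
  :class:`FieldSpec` lists);
* **arm_design** — every intervention arm with label, type, description,
  and intervention names;
* **participant_stats** — per-group values for a defined baseline measure;
* **trial_results** — reported values for a defined outcome.

The framework renders the request into a prompt, truncates the document to
a token budget (title and abstract first, then full text, then tables),
invokes a generative backend, and validates the parsed output against the
task schema.  Numbers are parsed leniently (thousands separators, percent
signs, and unit words stripped); derived quantities the source text does not
state verbatim are the backend's job — the framework validates, it never
recomputes.
"""

from __future__ import annotations

import logging
from typing import Any, Literal, Optional, Union

from pydantic import BaseModel, Field

from .backends import GenerativeBackend, attach_context, get_prompt, render_prompt
from .corpus_model import (ArmRecord, GroupSpec, ParticipantMeasureTruth,
                           ParticipantValue, RegistryData, StudyRecord,
                           TrialResultTruth, TrialResultValue)
from .errors import SchemaValidationError
from .parsing import parse_backend_json, parse_number

logger = logging.getLogger(__name__)

TASKS = ("characteristics", "arm_design", "participant_stats", "trial_results")


class FieldSpec(BaseModel):
    name: str
    value_kind: Literal["text", "number", "categorical"]
    description: str = ""


DEFAULT_CHARACTERISTICS_FIELDS: list[FieldSpec] = [
    FieldSpec(name="conditions", value_kind="text",
              description="Conditions studied (list of names)"),
    FieldSpec(name="interventions", value_kind="text",
              description="Interventions studied (list of names)"),
    FieldSpec(name="enrollment", value_kind="number",
              description="Number of participants enrolled"),
    FieldSpec(name="study_type", value_kind="categorical",
              description="Registry study type, e.g. INTERVENTIONAL"),
]


class CharacteristicsResult(BaseModel):
    """Field-name → extracted value; ``None`` marks a field the backend did
    not return or that failed to parse (scored incorrect, never fatal)."""

    values: dict[str, Any]


class ArmDesignResult(BaseModel):
    arms: list[ArmRecord]


class ParticipantStatsRequest(BaseModel):
    measure_definition: str
    parameter_type: str = ""
    unit: str = ""
    groups: list[GroupSpec] = Field(min_length=1)


class ParticipantStatsResult(BaseModel):
    results: list[ParticipantValue]


class TrialResultRequest(BaseModel):
    outcome_definition: str
    group_definition: str = ""
    parameter_type: str = ""
    unit: str = ""
    timeframe: str = ""
    denominator_unit: str = ""
    denominator_value: Optional[float] = Field(default=None, ge=0)


class TrialResultResult(BaseModel):
    results: list[TrialResultValue]


ExtractionRequest = Union[list[FieldSpec], None, ParticipantStatsRequest,
                          TrialResultRequest]
ExtractionResult = Union[CharacteristicsResult, ArmDesignResult,
                         ParticipantStatsResult, TrialResultResult]


def participant_request_from_truth(pm: ParticipantMeasureTruth
                                   ) -> ParticipantStatsRequest:
    """The request a reviewer would pose for a known registry measure
    (everything except the values)."""
    return ParticipantStatsRequest(
        measure_definition=pm.measure_definition,
        parameter_type=pm.parameter_type, unit=pm.unit, groups=pm.groups)


def trial_result_request_from_truth(tr: TrialResultTruth) -> TrialResultRequest:
    return TrialResultRequest(
        outcome_definition=tr.outcome_definition,
        group_definition=tr.group_definition,
        parameter_type=tr.parameter_type, unit=tr.unit,
        timeframe=tr.timeframe, denominator_unit=tr.denominator_unit,
        denominator_value=tr.denominator_value)


# ---------------------------------------------------------------------------
# Document truncation
# ---------------------------------------------------------------------------

def truncate_document(study: StudyRecord, budget_tokens: int = 30000) -> str:
    """Concatenate title, abstract, full text, then table blocks, truncated
    to a whitespace-token budget.

    The ordering guarantees the abstract is never sacrificed for full text.
    Documents already under budget are returned as the unchanged
    concatenation.  A model-tokenizer hook is deliberately not used: the
    whitespace count is deterministic everywhere.
    """
    if budget_tokens < 1:
        raise ValueError("budget_tokens must be >= 1")
    parts = [study.title, study.abstract]
    if study.full_text:
        parts.append(study.full_text)
    if study.table_text:
        parts.extend(study.table_text)
    document = "\n\n".join(p for p in parts if p)
    tokens = document.split()
    if len(tokens) <= budget_tokens:
        return document
    return " ".join(tokens[:budget_tokens])


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def _parse_characteristics(payload, fields: list[FieldSpec]
                           ) -> CharacteristicsResult:
    if not isinstance(payload, dict):
        raise SchemaValidationError("characteristics output must be an object",
                                    fields=[f.name for f in fields])
    bad: list[str] = []
    values: dict[str, Any] = {}
    for spec in fields:
        if spec.name not in payload:
            values[spec.name] = None  # absent marker
            continue
        raw = payload[spec.name]
        if spec.value_kind == "number":
            num = parse_number(raw)
            if num is None and raw is not None:
                logger.warning("characteristics field %r: unparseable number "
                               "%r; marked absent", spec.name, raw)
            values[spec.name] = num
        elif isinstance(raw, list):
            if not all(isinstance(x, str) for x in raw):
                bad.append(spec.name)
            else:
                values[spec.name] = raw
        elif isinstance(raw, str) or raw is None:
            values[spec.name] = raw
        else:
            bad.append(spec.name)
    if bad:
        raise SchemaValidationError(
            f"characteristics fields with invalid values: {bad}", fields=bad)
    return CharacteristicsResult(values=values)


def _parse_arms(payload) -> ArmDesignResult:
    if not isinstance(payload, dict) or not isinstance(payload.get("arms"), list):
        raise SchemaValidationError("arm design output must contain an "
                                    "'arms' list", fields=["arms"])
    arms: list[ArmRecord] = []
    labels: set[str] = set()
    for i, item in enumerate(payload["arms"]):
        try:
            arm = ArmRecord.model_validate(item)
        except Exception as err:
            raise SchemaValidationError(f"arm {i} is invalid: {err}",
                                        fields=[f"arms[{i}]"]) from err
        if arm.label in labels:
            raise SchemaValidationError(
                f"duplicate arm label: {arm.label!r}",
                fields=[f"arms[{i}].label"])
        labels.add(arm.label)
        arms.append(arm)
    return ArmDesignResult(arms=arms)


def _parse_participant_stats(payload, request: ParticipantStatsRequest
                             ) -> ParticipantStatsResult:
    if not isinstance(payload, dict) or not isinstance(payload.get("results"), list):
        raise SchemaValidationError("participant statistics output must "
                                    "contain a 'results' list",
                                    fields=["results"])
    known = {g.group_id for g in request.groups}
    out: list[ParticipantValue] = []
    for i, item in enumerate(payload["results"]):
        if not isinstance(item, dict):
            raise SchemaValidationError(f"result {i} must be an object",
                                        fields=[f"results[{i}]"])
        gid = item.get("group_id")
        if gid not in known:
            raise SchemaValidationError(
                f"result {i} cites unknown group_id {gid!r}",
                fields=[f"results[{i}].group_id"])
        value = parse_number(item.get("value"))
        if value is None:
            raise SchemaValidationError(
                f"result {i} has unparseable value {item.get('value')!r}",
                fields=[f"results[{i}].value"])
        out.append(ParticipantValue(group_id=gid, value=value,
                                    notes=str(item.get("notes", ""))))
    return ParticipantStatsResult(results=out)


def _parse_trial_results(payload) -> TrialResultResult:
    if not isinstance(payload, dict) or not isinstance(payload.get("results"), list):
        raise SchemaValidationError("trial result output must contain a "
                                    "'results' list", fields=["results"])
    out: list[TrialResultValue] = []
    for i, item in enumerate(payload["results"]):
        if not isinstance(item, dict):
            raise SchemaValidationError(f"result {i} must be an object",
                                        fields=[f"results[{i}]"])
        value = parse_number(item.get("value"))
        if value is None:
            raise SchemaValidationError(
                f"result {i} has unparseable value {item.get('value')!r}",
                fields=[f"results[{i}].value"])
        out.append(TrialResultValue(value=value,
                                    title=str(item.get("title", ""))))
    return TrialResultResult(results=out)


def _build_prompt(task: str, request: ExtractionRequest, document: str) -> str:
    if task == "characteristics":
        fields = request or DEFAULT_CHARACTERISTICS_FIELDS
        field_lines = "\n".join(
            f"- {f.name} ({f.value_kind}): {f.description}" for f in fields)
        return render_prompt(get_prompt(task),
                             {"fields": field_lines, "document": document})
    if task == "arm_design":
        return render_prompt(get_prompt(task), {"document": document})
    if task == "participant_stats":
        assert isinstance(request, ParticipantStatsRequest)
        group_lines = "\n".join(
            f"- {g.group_id}: {g.definition}" for g in request.groups)
        return render_prompt(get_prompt(task), {
            "measure_definition": request.measure_definition,
            "parameter_type": request.parameter_type, "unit": request.unit,
            "groups": group_lines, "document": document})
    assert isinstance(request, TrialResultRequest)
    return render_prompt(get_prompt(task), {
        "outcome_definition": request.outcome_definition,
        "group_definition": request.group_definition,
        "parameter_type": request.parameter_type, "unit": request.unit,
        "timeframe": request.timeframe, "document": document})


def extract_structured(task: str, request: ExtractionRequest,
                       study: StudyRecord, backend: GenerativeBackend,
                       seed: int = 0, budget_tokens: int = 30000,
                       truth_index: int = 0) -> ExtractionResult:
    """Run one extraction task on one study through the backend and
    validate the output against the task schema.

    ``truth_index`` selects which registry measure/outcome a bound oracle
    resolves when a study reports several.
    """
    if task not in TASKS:
        raise ValueError(f"unknown extraction task {task!r}")
    document = truncate_document(study, budget_tokens)
    prompt = _build_prompt(task, request, document)
    context = {"task": task, "study_id": study.study_id}
    if task == "participant_stats":
        context["measure_index"] = truth_index
    elif task == "trial_results":
        context["outcome_index"] = truth_index
    raw = backend.complete(attach_context(prompt, **context), seed=seed)
    payload = parse_backend_json(raw)
    if task == "characteristics":
        return _parse_characteristics(payload,
                                      request or DEFAULT_CHARACTERISTICS_FIELDS)
    if task == "arm_design":
        return _parse_arms(payload)
    if task == "participant_stats":
        assert isinstance(request, ParticipantStatsRequest)
        return _parse_participant_stats(payload, request)
    return _parse_trial_results(payload)


def truth_as_result(task: str, truth: RegistryData,
                    truth_index: int = 0) -> ExtractionResult:
    """Registry ground truth in the same shape extraction results take,
    for scoring predictions against it."""
    if task == "characteristics":
        return CharacteristicsResult(values={
            "conditions": truth.conditions,
            "interventions": truth.interventions,
            "enrollment": float(truth.enrollment),
            "study_type": truth.study_type,
        })
    if task == "arm_design":
        return ArmDesignResult(arms=truth.arms)
    if task == "participant_stats":
        return ParticipantStatsResult(
            results=truth.participant_measures[truth_index].results)
    if task == "trial_results":
        return TrialResultResult(
            results=truth.outcome_results[truth_index].results)
    raise ValueError(f"unknown extraction task {task!r}")
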