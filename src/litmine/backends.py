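"""Generative and embedding backend contracts, deterministic oracle test
doubles, and the versioned prompt-template registry.

Pipelines talk to a :class:`GenerativeBackend` only through rendered text
prompts, so a fine-tuned model served over HTTP and the offline oracle are
interchangeable.  Each rendered prompt carries a machine-readable context
line (task name plus the ids involved); the oracle backends resolve those
ids against the ground truth planted in their bound corpus and answer with
schema-valid output, which makes every pipeline stage verifiable without a
trained model.  The noisy oracle corrupts the oracle's answers at a
configurable rate and is the workhorse for calibration experiments.
"""

from __future__ import annotations

import hashlib
import json
import logging
import string
import time
import urllib.request
from typing import Optional, Protocol, runtime_checkable

import numpy as np
from pydantic import BaseModel

from .corpus_model import LinkedCorpus, tokenize
from .errors import OracleError, PromptError

logger = logging.getLogger(__name__)

CONTEXT_MARKER = "###CONTEXT "


# ---------------------------------------------------------------------------
# Backend contracts
# ---------------------------------------------------------------------------

@runtime_checkable
class GenerativeBackend(Protocol):
    """Text-completion contract.  Deterministic implementations must return
    identical text for identical ``(prompt, seed)``."""

    deterministic: bool

    def complete(self, prompt: str, seed: int = 0,
                 temperature: float = 0.0,
                 max_len: Optional[int] = None) -> str: ...


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Fixed-length text embedding contract."""

    def embed(self, text: str) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# Prompt templates
# ---------------------------------------------------------------------------

class PromptTemplate(BaseModel):
    """A named, versioned prompt with ``{placeholder}`` variables.

    Rendering fails loudly on a missing placeholder; instruction datasets
    record the version tag so emitted records are traceable to the exact
    template wording."""

    task: str
    template: str
    version: str = "v1"

    def placeholders(self) -> list[str]:
        return [f for _, f, _, _ in string.Formatter().parse(self.template)
                if f is not None]


def render_prompt(template: PromptTemplate, variables: dict) -> str:
    """Substitute ``variables`` into the template; any missing placeholder
    raises :class:`PromptError` naming it."""
    for name in template.placeholders():
        if name not in variables:
            raise PromptError(name)
    return template.template.format(**variables)


PROMPTS: dict[str, PromptTemplate] = {
    "term_extraction": PromptTemplate(
        task="term_extraction",
        template=(
            "Read the clinical study below and extract up to ten population "
            "keywords and up to ten intervention keywords that a searcher "
            "could use to retrieve it.  Respond with a JSON object with keys "
            "'population' and 'intervention', each a list of strings.\n\n"
            "Title: {title}\nAbstract: {abstract}"
        ),
    ),
    "query_generation": PromptTemplate(
        task="query_generation",
        template=(
            "You design boolean literature-search strategies.  Given the "
            "research question below, produce keyword groups for retrieving "
            "all relevant studies.  Respond with a JSON object with key "
            "'groups': a list of objects, each with 'population' and "
            "'intervention' keyword lists (one group per distinct study "
            "profile you anticipate).\n\n"
            "Population: {population}\nIntervention: {intervention}\n"
            "Comparator: {comparator}\nOutcome: {outcome}"
        ),
    ),
    "eligibility": PromptTemplate(
        task="eligibility",
        template=(
            "Assess the study below against each eligibility criterion of a "
            "systematic review.  For every criterion answer with one of YES, "
            "PARTIAL, UNCERTAIN, NO and a short rationale.  Respond with a "
            "JSON object with key 'assessments': a list of objects with "
            "'label' and 'rationale', in criterion order.\n\n"
            "Criteria:\n{criteria}\n\nTitle: {title}\nAbstract: {abstract}"
        ),
    ),
    "characteristics": PromptTemplate(
        task="characteristics",
        template=(
            "Extract the following study characteristics from the document. "
            "Respond with a JSON object keyed by field name.\n\n"
            "Fields:\n{fields}\n\nDocument:\n{document}"
        ),
    ),
    "arm_design": PromptTemplate(
        task="arm_design",
        template=(
            "Extract the design of every study arm from the document. "
            "Respond with a JSON object with key 'arms': a list of objects "
            "with 'label', 'arm_type', 'description', and "
            "'intervention_names'.\n\nDocument:\n{document}"
        ),
    ),
    "participant_stats": PromptTemplate(
        task="participant_stats",
        template=(
            "Extract participant statistics from the document for the "
            "measure defined below.  Respond with a JSON object with key "
            "'results': a list of objects with 'group_id', 'value', and "
            "'notes'.\n\nMeasure: {measure_definition}\n"
            "Parameter type: {parameter_type}\nUnit: {unit}\n"
            "Groups:\n{groups}\n\nDocument:\n{document}"
        ),
    ),
    "trial_results": PromptTemplate(
        task="trial_results",
        template=(
            "Extract the trial results from the document for the outcome "
            "defined below.  Respond with a JSON object with key 'results': "
            "a list of objects with 'value' and 'title'.\n\n"
            "Outcome: {outcome_definition}\nGroups: {group_definition}\n"
            "Parameter type: {parameter_type}\nUnit: {unit}\n"
            "Timeframe: {timeframe}\n\nDocument:\n{document}"
        ),
    ),
}


def get_prompt(task: str) -> PromptTemplate:
    return PROMPTS[task]


def attach_context(prompt: str, **context) -> str:
    """Append the machine-readable context line oracle backends resolve."""
    return prompt + "\n" + CONTEXT_MARKER + json.dumps(context, sort_keys=True)


def parse_context(prompt: str) -> dict:
    for line in reversed(prompt.splitlines()):
        if line.startswith(CONTEXT_MARKER):
            return json.loads(line[len(CONTEXT_MARKER):])
    return {}


def _fenced(obj) -> str:
    return "```json\n" + json.dumps(obj, indent=1, sort_keys=True) + "\n```"


# ---------------------------------------------------------------------------
# Oracle backends
# ---------------------------------------------------------------------------

def _phrase_in(needle: tuple[str, ...], haystack: tuple[str, ...]) -> bool:
    n = len(needle)
    return n > 0 and any(haystack[i:i + n] == needle
                         for i in range(len(haystack) - n + 1))


class OracleBackend:
    """Answers prompts from the ground truth planted in its bound corpus.

    Included studies receive all-YES eligibility analyses; other candidates
    receive PARTIAL for criteria whose element terms appear in their text and
    NO otherwise, so no non-included candidate can reach the maximal score.
    Term-extraction and query-generation prompts are answered with the
    planted keyword sets; extraction prompts reproduce ``registry_truth``.
    """

    deterministic = True

    def __init__(self, corpus: LinkedCorpus):
        self.corpus = corpus
        self._label_cache: dict[tuple[str, str], list[str]] = {}

    # -- per-task truth reconstruction ------------------------------------
    def _term_extraction(self, ctx: dict) -> dict:
        sid = ctx["study_id"]
        planted = self.corpus.planted_terms.get(sid)
        if planted is None:
            raise OracleError(f"no planted terms for study {sid}")
        return {"population": planted.population,
                "intervention": planted.intervention}

    def _query_groups(self, ctx: dict) -> dict:
        rid = ctx["review_id"]
        if rid not in self.corpus.inclusion_truth:
            raise OracleError(f"unknown review {rid}")
        groups = []
        for sid in sorted(self.corpus.inclusion_truth[rid]):
            planted = self.corpus.planted_terms.get(sid)
            if planted is None:
                raise OracleError(f"no planted terms for study {sid}")
            groups.append({"population": planted.population,
                           "intervention": planted.intervention})
        return {"groups": groups}

    def eligibility_labels(self, review_id: str, study_id: str,
                           elements: list[str]) -> list[str]:
        """Criterion labels for a candidate, derived from corpus truth."""
        key = (review_id, study_id)
        if key not in self._label_cache:
            if review_id not in self.corpus.inclusion_truth:
                raise OracleError(f"unknown review {review_id}")
            try:
                tokens = self.corpus.token_index()[study_id]
            except KeyError:
                raise OracleError(f"unknown study {study_id}") from None
            if study_id in self.corpus.inclusion_truth[review_id]:
                labels = {e: "YES" for e in "PICO"}
            else:
                elem_terms = self.corpus.element_terms.get(review_id, {})
                labels = {}
                for e in "PICO":
                    terms = elem_terms.get(e, [])
                    present = terms and all(
                        _phrase_in(tokenize(t), tokens) for t in terms)
                    labels[e] = "PARTIAL" if present else "NO"
            self._label_cache[key] = labels
        labels = self._label_cache[key]
        return [labels[e] for e in elements]

    def _eligibility(self, ctx: dict) -> dict:
        labels = self.eligibility_labels(ctx["review_id"], ctx["study_id"],
                                         ctx["elements"])
        return {"assessments": [
            {"label": lab,
             "rationale": f"Ground-truth derived assessment for element {e}."}
            for lab, e in zip(labels, ctx["elements"])
        ]}

    def _registry(self, sid: str):
        try:
            study = self.corpus.study(sid)
        except KeyError:
            raise OracleError(f"unknown study {sid}") from None
        if study.registry_truth is None:
            raise OracleError(f"study {sid} has no registry truth")
        return study.registry_truth

    def _extraction(self, task: str, ctx: dict) -> dict:
        truth = self._registry(ctx["study_id"])
        if task == "characteristics":
            return {"conditions": truth.conditions,
                    "interventions": truth.interventions,
                    "enrollment": truth.enrollment,
                    "study_type": truth.study_type}
        if task == "arm_design":
            return {"arms": [a.model_dump() for a in truth.arms]}
        if task == "participant_stats":
            pm = truth.participant_measures[ctx.get("measure_index", 0)]
            return {"results": [r.model_dump() for r in pm.results]}
        if task == "trial_results":
            tr = truth.outcome_results[ctx.get("outcome_index", 0)]
            return {"results": [r.model_dump() for r in tr.results]}
        raise OracleError(f"unknown extraction task {task}")

    # -- contract ----------------------------------------------------------
    def complete(self, prompt: str, seed: int = 0, temperature: float = 0.0,
                 max_len: Optional[int] = None) -> str:
        ctx = parse_context(prompt)
        task = ctx.get("task")
        if task == "term_extraction":
            return _fenced(self._term_extraction(ctx))
        if task == "query_generation":
            return _fenced(self._query_groups(ctx))
        if task == "eligibility":
            return _fenced(self._eligibility(ctx))
        if task in ("characteristics", "arm_design", "participant_stats",
                    "trial_results"):
            return _fenced(self._extraction(task, ctx))
        raise OracleError(f"oracle cannot resolve prompt task {task!r}")


def _hash32(*parts: str) -> int:
    h = hashlib.blake2s("|".join(parts).encode("utf-8"), digest_size=4)
    return int.from_bytes(h.digest(), "big")


class NoisyOracleBackend(OracleBackend):
    """Oracle corrupted at rate ``error_rate``; exactly the oracle at rate 0.

    Eligibility: each YES label flips to NO independently with probability
    ``error_rate``.  Query generation: each per-study keyword group is
    dropped independently with probability ``error_rate`` (at least one group
    is always kept).  Corruptions are a pure function of the backend seed,
    the call seed, and the ids involved, so runs are reproducible.
    """

    def __init__(self, corpus: LinkedCorpus, error_rate: float, seed: int = 0):
        super().__init__(corpus)
        if not 0.0 <= error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        self.error_rate = error_rate
        self.seed = seed

    def _rng(self, call_seed: int, *parts: str) -> np.random.Generator:
        return np.random.default_rng(
            [self.seed & 0x7FFFFFFF, call_seed & 0x7FFFFFFF,
             _hash32(*parts)])

    def complete(self, prompt: str, seed: int = 0, temperature: float = 0.0,
                 max_len: Optional[int] = None) -> str:
        ctx = parse_context(prompt)
        task = ctx.get("task")
        if task == "eligibility":
            payload = self._eligibility(ctx)
            rng = self._rng(seed, "elig", ctx["review_id"], ctx["study_id"])
            for item in payload["assessments"]:
                if item["label"] == "YES" and rng.random() < self.error_rate:
                    item["label"] = "NO"
                    item["rationale"] = "Assessment corrupted by noise model."
            return _fenced(payload)
        if task == "query_generation":
            payload = self._query_groups(ctx)
            rng = self._rng(seed, "query", ctx["review_id"])
            keep = [g for g in payload["groups"]
                    if rng.random() >= self.error_rate]
            if not keep:
                keep = [payload["groups"][int(rng.integers(len(payload["groups"])))]]
            return _fenced({"groups": keep})
        return super().complete(prompt, seed=seed, temperature=temperature,
                                max_len=max_len)


class FunctionBackend:
    """Wraps a ``(prompt, seed) -> text`` callable; useful for injecting
    hand-written responses in tests."""

    deterministic = True

    def __init__(self, fn):
        self._fn = fn

    def complete(self, prompt: str, seed: int = 0, temperature: float = 0.0,
                 max_len: Optional[int] = None) -> str:
        return self._fn(prompt, seed)


# ---------------------------------------------------------------------------
# Deterministic embedding backend
# ---------------------------------------------------------------------------

class HashedNgramEmbedder:
    """Character-3-gram count vector, hashed into a fixed dimension.

    Deterministic and dependency-free, so cosine similarities are exactly
    reproducible across machines.  An API embedding backend satisfying the
    same contract is a drop-in replacement.
    """

    def __init__(self, dim: int = 65536):
        self.dim = dim

    @staticmethod
    def ngrams(text: str) -> list[str]:
        s = " ".join(text.lower().split())
        if len(s) < 3:
            return [s] if s else []
        return [s[i:i + 3] for i in range(len(s) - 2)]

    def _index(self, gram: str) -> int:
        h = hashlib.blake2s(gram.encode("utf-8"), digest_size=8)
        return int.from_bytes(h.digest(), "big") % self.dim

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        for gram in self.ngrams(text):
            vec[self._index(gram)] += 1.0
        return vec


# ---------------------------------------------------------------------------
# HTTP API adapter (network-gated; not exercised by the test suite)
# ---------------------------------------------------------------------------

class OpenAIChatBackend:
    """Minimal OpenAI-compatible chat-completions adapter with bounded
    retry.  Requires network access and a credential; intended for swapping
    a served model into the same pipeline code paths as the oracle."""

    deterministic = False

    def __init__(self, endpoint: str, model: str, api_key: str,
                 max_retries: int = 3, backoff_s: float = 2.0):
        self.endpoint = endpoint
        self.model = model
        self.api_key = api_key
        self.max_retries = max_retries
        self.backoff_s = backoff_s

    def complete(self, prompt: str, seed: int = 0, temperature: float = 0.0,
                 max_len: Optional[int] = None) -> str:
        body = {
            "model": self.model,
            "messages": [{"role": "user", "content": prompt}],
            "temperature": temperature,
            "seed": seed,
        }
        if max_len is not None:
            body["max_tokens"] = max_len
        data = json.dumps(body).encode("utf-8")
        last_err: Exception | None = None
        for attempt in range(self.max_retries):
            try:
                req = urllib.request.Request(
                    self.endpoint, data=data,
                    headers={"Content-Type": "application/json",
                             "Authorization": f"Bearer {self.api_key}"})
                with urllib.request.urlopen(req, timeout=120) as resp:
                    payload = json.loads(resp.read().decode("utf-8"))
                text = payload["choices"][0]["message"]["content"]
                logger.info("backend call ok (prompt sha=%s, attempt=%d)",
                            hashlib.sha256(prompt.encode()).hexdigest()[:12],
                            attempt)
                return text
            except Exception as err:  # noqa: BLE001 - retried, then re-raised
                last_err = err
                logger.warning("backend call failed (attempt %d): %s",
                               attempt, err)
                time.sleep(self.backoff_s * (attempt + 1))
        raise last_err  # type: ignore[misc]
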