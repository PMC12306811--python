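"""Shared parsing helpers: backend JSON payloads and lenient numerals."""

from __future__ import annotations

import json
import re
from typing import Optional

from .errors import BackendOutputError

_FENCE_RE = re.compile(r"```(?:json)?\s*(.*?)```", re.DOTALL)


def parse_backend_json(raw: str) -> dict | list:
    """Parse a backend response as JSON, accepting fenced code blocks.

    Raises :class:`BackendOutputError` (carrying the raw output) when no
    JSON document can be recovered.
    """
    candidates = [m.strip() for m in _FENCE_RE.findall(raw)]
    candidates.append(raw.strip())
    for cand in candidates:
        if not cand:
            continue
        try:
            return json.loads(cand)
        except json.JSONDecodeError:
            continue
    raise BackendOutputError("backend output is not valid JSON", raw_output=raw)


_NUM_RE = re.compile(r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


def parse_number(value) -> Optional[float]:
    """Lenient numeric parse: strips thousands separators, percent signs,
    and surrounding unit words (``"12.5 years"`` → 12.5).  Returns None when
    no single number can be recovered."""
    if isinstance(value, bool):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        return None
    text = value.strip().replace(",", "").replace("%", " ")
    matches = _NUM_RE.findall(text)
    if len(matches) != 1:
        return None
    # reject strings whose non-numeric remainder is not unit-like words
    rest = _NUM_RE.sub(" ", text)
    if re.search(r"\d", rest):
        return None
    try:
        return float(matches[0])
    except ValueError:
        return None
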