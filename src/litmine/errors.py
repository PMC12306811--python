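"""Exception hierarchy for litmine.

Every error raised by the package derives from :class:`LitmineError` so
callers can catch pipeline failures without masking programming errors.
"""

from __future__ import annotations


class LitmineError(Exception):
    """Base class for all litmine errors."""


class ConfigurationError(LitmineError):
    """Invalid configuration; the message names the offending field."""


class BackendOutputError(LitmineError):
    """A generative backend produced output the consumer could not parse.

    The raw backend output is attached so callers can log or inspect it.
    """

    def __init__(self, message: str, raw_output: str = ""):
        super().__init__(message)
        self.raw_output = raw_output


class GenerationError(BackendOutputError):
    """Query generation failed (unparseable output or missing keyword group)."""


class AssemblyError(LitmineError):
    """A boolean query could not be assembled from term sets."""


class MappingError(LitmineError):
    """An eligibility label outside the closed label set was encountered."""


class AggregationError(LitmineError):
    """Score aggregation was requested on an empty assessment list."""


class UndefinedMetricError(LitmineError):
    """A metric is undefined for the given inputs (e.g. empty truth set)."""


class SchemaValidationError(LitmineError):
    """Structured extraction output violated its task schema.

    ``fields`` lists the offending field names/paths.
    """

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []


class PromptError(LitmineError):
    """A prompt template could not be rendered; the message names the
    missing placeholder."""


class OracleError(LitmineError):
    """The oracle backend was asked about ids it cannot resolve in its
    bound corpus.  This indicates a test/setup bug, not a runtime state."""
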