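"""Exception hierarchy shared across the pipeline stages."""


class OCTargetsError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(OCTargetsError):
    """Invalid simulation or pipeline configuration."""


class InputFormatError(OCTargetsError):
    """A supplied table or file violates its documented format."""


class MergeError(OCTargetsError):
    """Cross-study merge could not be performed (e.g. empty gene overlap)."""


class DegenerateBatchError(OCTargetsError):
    """A batch has too few samples for location-scale adjustment."""


class DesignError(OCTargetsError):
    """Experimental design unsuitable for the requested fit."""


class SampleSizeError(OCTargetsError):
    """Too few samples for the requested estimator."""


class SignificanceError(OCTargetsError):
    """Null-model fit for edge significance failed to converge."""


class EmptyGraphError(OCTargetsError):
    """A relation file yielded no usable signed edges."""


class QueryParseError(OCTargetsError):
    """A boolean query string could not be parsed."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class AccountingError(OCTargetsError):
    """Inconsistent counts (e.g. a negative contingency-table cell)."""


class ReconciliationError(OCTargetsError):
    """Gene universes of upstream results could not be reconciled."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []
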