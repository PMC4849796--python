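"""Exception hierarchy shared across the package."""


class SeapatchError(Exception):
    """Base class for all package errors."""


class SchemaError(SeapatchError, ValueError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(SeapatchError, ValueError):
    """A value violates a contract (negative count, asymmetric weights, ...)."""


class DomainError(SeapatchError, ValueError):
    """A statistic is undefined for the given input (degenerate denominator)."""


class PipelineError(SeapatchError, RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""
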