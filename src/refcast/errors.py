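"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`RefcastError`
so callers (and the CLI) can distinguish bad inputs from genuine bugs.
"""


class RefcastError(Exception):
    """Base class for all refcast errors."""


class InvalidConfigError(RefcastError, ValueError):
    """A configuration object violates its invariants."""


class InvalidArgumentError(RefcastError, ValueError):
    """An operation argument is out of its documented domain."""


class InsufficientDataError(RefcastError, ValueError):
    """The input series is too short for the requested operation."""


class DegenerateInputError(RefcastError, ValueError):
    """Input on which the statistic or test is mathematically undefined."""


class FitFailureError(RefcastError, RuntimeError):
    """A model fit failed to converge; carries the attempted order."""

    def __init__(self, message: str, order=None):
        super().__init__(message)
        self.order = order


class NoModelError(RefcastError, RuntimeError):
    """Every candidate model in a search failed to fit."""


class UndefinedMetricError(RefcastError, ValueError):
    """A score metric is undefined for the given inputs (e.g. all-zero actuals)."""


class ContractViolationError(RefcastError, RuntimeError):
    """An external forecaster adapter broke the adapter contract."""


class SchemaError(RefcastError, ValueError):
    """A CSV file does not match the expected schema."""
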