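"""Exception hierarchy for setgrowth.

All package errors derive from :class:`SetGrowthError` so callers can catch
pipeline failures with a single except clause while still distinguishing
schema problems from numerical/domain ones.
"""


class SetGrowthError(Exception):
    """Base class for all setgrowth errors."""


class SchemaError(SetGrowthError):
    """A required column or config key is absent or mis-typed."""


class ParseError(SetGrowthError):
    """A cell value could not be parsed (non-numeric trait, bad time)."""


class IntegrityError(SetGrowthError):
    """A dataset invariant is violated (e.g. duplicated subject-time key)."""


class DomainError(SetGrowthError):
    """A value is outside the mathematical domain of an operation
    (e.g. nonpositive trait value under a log transform)."""


class ParameterError(SetGrowthError):
    """An argument is outside its legal range (df, breakpoints, lags...)."""


class StartValueError(ParameterError):
    """Self-start for a nonlinear fit failed on degenerate data."""


class MissingEndpointError(SetGrowthError):
    """An interval endpoint time has no observed or imputed value."""


class EstimabilityError(SetGrowthError):
    """A model cell is empty / a linear function is not estimable."""


class EmptyResultError(SetGrowthError):
    """An operation produced no rows (e.g. no overlapping keys)."""
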