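"""Typed exceptions and warnings shared across the pipeline."""


class PlsdeError(Exception):
    """Base class for all package errors."""


class ParameterError(PlsdeError, ValueError):
    """A configuration or function parameter violates its contract."""


class DataError(PlsdeError, ValueError):
    """Input data violates an invariant (missing value, bad label, ...)."""


class NoSignalWarning(UserWarning):
    """The predictor block carries no covariance with the response."""


class DegenerateStatisticError(PlsdeError, ValueError):
    """A test statistic is undefined for the given data (zero variance)."""
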