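"""Exception hierarchy shared across the package."""


class PhotothermalError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PhotothermalError, ValueError):
    """A numeric argument violates its domain (non-finite, wrong sign, ...)."""


class InvalidInputError(PhotothermalError, ValueError):
    """A data input (observation, table, trace) violates its contract."""


class InsufficientDataError(PhotothermalError, ValueError):
    """Not enough usable observations to attempt a fit."""


class ConvergenceError(PhotothermalError, RuntimeError):
    """An iterative solver failed to converge from every initialization."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class NumericalSolutionError(PhotothermalError, RuntimeError):
    """A closed-form solve produced no admissible real root."""


class NoBreakpointError(PhotothermalError, RuntimeError):
    """No flat/steep contrast strong enough to declare a breakpoint."""


class ConfigurationError(PhotothermalError, ValueError):
    """A configuration object is incomplete or inconsistent."""


class SchemaError(PhotothermalError, ValueError):
    """A tabular input lacks required columns."""

    def __init__(self, message, available=None):
        if available is not None:
            message = f"{message} (available columns: {sorted(available)})"
        super().__init__(message)
        self.available = available


class AggregationError(PhotothermalError, ValueError):
    """Results being pooled are mutually inconsistent."""
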