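"""Exception hierarchy for adipoflux."""


class AdipofluxError(Exception):
    """Base class for all package errors."""


class SchemaError(AdipofluxError):
    """Tabular input violates the study-table schema (missing column,
    negative concentration, duplicate key...)."""


class InsufficientDataError(AdipofluxError):
    """Too few samples to build a forcing function or dispersion."""


class ParameterError(AdipofluxError):
    """Model parameters outside their admissible domain."""


class DegenerateDelayError(ParameterError):
    """A delay time constant of zero was supplied to a delay chain;
    use the explicit no-delay bypass instead."""


class InitializationError(AdipofluxError):
    """No non-negative fasting fixed point exists for the supplied
    parameters and forcings.

    ``violation`` quantifies how far the constraint is missed, so that
    optimizers receive a graded (rather than flat) penalty and can climb
    back into the feasible region.
    """

    def __init__(self, message: str, violation: float = 1.0):
        super().__init__(message)
        self.violation = violation


class IntegrationError(AdipofluxError):
    """ODE solver failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time
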