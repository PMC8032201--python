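"""Exception hierarchy for slowphase."""


class SlowPhaseError(Exception):
    """Base class for all slowphase errors."""


class ConfigurationError(SlowPhaseError):
    """A model or run configuration is invalid (missing parameter, unknown name)."""


class DomainError(SlowPhaseError):
    """An input lies outside the domain where the operation is defined."""


class IntegrationError(SlowPhaseError):
    """Numerical integration failed (step-size underflow, non-finite state)."""

    def __init__(self, message, t_reached=None):
        super().__init__(message)
        self.t_reached = t_reached


class ConvergenceError(SlowPhaseError):
    """An iterative solve (Newton, continuation) did not converge."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class BasinError(SlowPhaseError):
    """A point did not converge to the limit cycle within the allotted window."""


class PrecisionError(SlowPhaseError):
    """A requested tolerance cannot be met at the smallest usable discretization."""


class DegenerateLinearizationError(SlowPhaseError):
    """The phase gradient is too close to zero to define an isochron tangent."""
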