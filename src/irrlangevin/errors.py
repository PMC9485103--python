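"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when arguments violate a documented precondition."""


class ConfigurationError(InvalidInputError):
    """Raised when a sampler/perturbation combination is inconsistent,
    e.g. a metric-requiring kind on a metric-free target."""


class ChainFailureError(RuntimeError):
    """Raised when more than the tolerated fraction of an ensemble's chains
    leave the admissible domain; carries the partial reports."""

    def __init__(self, message, reports=None):
        super().__init__(message)
        self.reports = reports or {}


class NumericalDomainError(FloatingPointError):
    """Raised when a simulation leaves the admissible domain.

    Carries the step index and offending state so failures in long runs
    can be located.
    """

    def __init__(self, message, step=None, state=None):
        super().__init__(message)
        self.step = step
        self.state = state
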