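"""Exception hierarchy used across the package."""


class LocsimError(Exception):
    """Base class for all package errors."""


class DomainError(LocsimError, ValueError):
    """An argument is outside the physical domain of an operation."""


class ConfigurationError(LocsimError, ValueError):
    """An experiment configuration is malformed or inconsistent."""


class DegenerateParameterError(LocsimError, ValueError):
    """A parameter combination makes a formula degenerate (e.g. a vanishing
    denominator in the shell homogenization or a zero-length collision
    normal)."""


class NumericalFailureError(LocsimError, RuntimeError):
    """The integration produced non-finite state; carries the step index."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step
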