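"""Exception hierarchy shared across the package."""


class SrmptError(Exception):
    """Base class for all package-specific errors."""


class EqnParseError(SrmptError):
    """An EQN model file line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructuralError(SrmptError):
    """A model tree is structurally incomplete (branch probabilities do not sum to 1)."""


class ConstraintError(SrmptError):
    """A constraint set is contradictory, cyclic, or references unknown parameters."""


class DomainError(SrmptError):
    """A parameter value lies outside [0, 1] or is otherwise out of domain."""


class DataError(SrmptError):
    """Observed data violate a precondition (e.g. an all-zero tree)."""


class InversionError(SrmptError):
    """The closed-form saturated inversion is undefined for these frequencies."""


class ConvergenceError(SrmptError):
    """The optimizer failed to converge after all restarts."""
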