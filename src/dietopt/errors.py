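"""Exception types shared across the package."""


class DietOptError(Exception):
    """Base class for package errors."""


class InvalidInputError(DietOptError, ValueError):
    """An argument violates a documented precondition."""


class UnknownFoodError(DietOptError, LookupError):
    """A diet refers to a food id with no composition or price."""


class ConfigurationError(DietOptError, RuntimeError):
    """Inconsistent model configuration (missing bounds, references, rows)."""


class DiagnosisError(DietOptError, RuntimeError):
    """Limiting-constraint diagnosis could not explain an infeasibility."""


class SolverError(DietOptError, RuntimeError):
    """The LP solver failed for a reason other than infeasibility."""


class GeneratorError(DietOptError, RuntimeError):
    """Synthetic-data construction failed after bounded retries."""
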