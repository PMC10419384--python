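"""Package-wide exception types.

Exit-code mapping used by the CLI: ValidationError and its subclasses map to
exit code 2 (bad input), numerical failures (SeparationError, RankDeficientError,
UndefinedDiagnosticError) map to exit code 3.
"""


class OlfactError(Exception):
    """Base class for all package errors."""


class ValidationError(OlfactError, ValueError):
    """Invalid user input (out-of-range threshold, bad probability vector, ...)."""


class LayoutError(ValidationError):
    """Synthetic glomerulus layout is geometrically invalid (overlap / out of frame)."""


class SeparationError(OlfactError, RuntimeError):
    """Logistic fit diverged: complete or quasi-complete separation."""


class RankDeficientError(OlfactError, RuntimeError):
    """Observed information matrix is singular (collinear design)."""


class UndefinedDiagnosticError(OlfactError, RuntimeError):
    """A 2x2 diagnostic (odds ratio, sensitivity, specificity) is undefined."""
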