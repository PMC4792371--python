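"""Exception hierarchy for clotrheo.

All package errors derive from :class:`ClotRheoError` so callers can catch
one base class; the subclasses mirror the failure modes of the pipeline
(invalid inputs, degenerate deformations, integration blow-up, fitting
non-convergence, insufficient or degenerate data).
"""


class ClotRheoError(Exception):
    """Base class for all clotrheo errors."""


class InvalidInputError(ClotRheoError, ValueError):
    """Malformed or non-finite input data."""


class InvalidParameterError(ClotRheoError, ValueError):
    """Model parameters outside their admissible domain."""


class InvalidStateError(ClotRheoError, ValueError):
    """Model state violating its invariants (e.g. x outside (0, 1])."""


class DegenerateDeformationError(ClotRheoError, ValueError):
    """Singular deformation gradient or loss of tensor invertibility."""


class IntegrationFailureError(ClotRheoError, RuntimeError):
    """Time integration failed (non-finite state or loss of positive
    definiteness after repair)."""

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class InsufficientDataError(ClotRheoError, ValueError):
    """Trace too short or window too narrow for the requested analysis."""


class DegenerateFeatureError(ClotRheoError, ValueError):
    """Feature extraction hit a division by (near) zero."""


class UndefinedPhaseError(ClotRheoError, ValueError):
    """Phase angle undefined (both moduli zero)."""


class FitFailureError(ClotRheoError, RuntimeError):
    """Nonlinear least squares failed to converge."""

    def __init__(self, message: str, residual_report=None):
        super().__init__(message)
        self.residual_report = residual_report


class StageFailureError(FitFailureError):
    """A stage of the stepwise fitting procedure failed."""

    def __init__(self, stage: str, message: str, residual_report=None):
        super().__init__(f"stage '{stage}': {message}", residual_report)
        self.stage = stage


class ParseError(ClotRheoError, ValueError):
    """Malformed trace/parameter file."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
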