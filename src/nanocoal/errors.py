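"""Exception hierarchy for the package.

All errors derive from :class:`NanocoalError` so callers (and the CLI) can
distinguish validation problems (:class:`InvalidInputError`,
:class:`InvalidStateError`) from numerical failures
(:class:`IntegrationError`, :class:`FitError`, :class:`CalibrationError`,
:class:`InfeasibleTargetError`).
"""

from __future__ import annotations


class NanocoalError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NanocoalError, ValueError):
    """An argument violates a precondition; the message names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class InvalidStateError(NanocoalError, ValueError):
    """An internal state (e.g. a surface coverage) violates an invariant."""


class IntegrationError(NanocoalError, RuntimeError):
    """ODE integration failed; carries the last accepted state."""

    def __init__(self, message: str, last_state=None):
        self.last_state = last_state
        super().__init__(message)


class CalibrationError(NanocoalError, RuntimeError):
    """Collision-clock calibration could not place the diameter maximum.

    ``diagnostic`` holds a coarse (concentration, diameter) scan of the
    corrected curve to help diagnose why no interior maximum exists.
    """

    def __init__(self, message: str, diagnostic=None):
        self.diagnostic = diagnostic
        super().__init__(message)


class InsufficientDataError(NanocoalError, ValueError):
    """Too few data points for the requested fit."""


class FitError(NanocoalError, RuntimeError):
    """All optimizer starts failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        self.diagnostics = diagnostics
        super().__init__(message)


class InfeasibleTargetError(NanocoalError, ValueError):
    """A design target cannot be reached by the forward model.

    ``achievable`` reports the closest attainable value (e.g. the maximum
    diameter of a unimodal corrected curve) when known.
    """

    def __init__(self, message: str, achievable: float | None = None):
        self.achievable = achievable
        super().__init__(message)
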