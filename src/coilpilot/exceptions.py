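"""Package-wide exception types."""


class CoilPilotError(Exception):
    """Base class for all coilpilot errors."""


class DegenerateGeometryError(CoilPilotError, ValueError):
    """Landmark configuration does not admit a well-posed target computation.

    Raised when the preauricular axis is (near-)perpendicular to the camera
    x-axis, when the combined arc angle approaches 90 degrees so the tangent
    in the target equation blows up, or when the landmark triangle collapses.
    """


class NoContactError(CoilPilotError, ValueError):
    """Total adjusted sensor load is at or below the contact epsilon."""


class ConvergenceError(CoilPilotError, RuntimeError):
    """An iterative search failed to converge within its bounds.

    Carries the search ``history`` so the caller can inspect every level
    that was tested before the failure.
    """

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = list(history) if history is not None else []


class SchemaError(CoilPilotError, ValueError):
    """A file did not match its expected schema; names the offending field."""
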