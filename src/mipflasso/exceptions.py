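"""Package-specific exception types."""


class MipfLassoError(Exception):
    """Base class for errors raised by this package."""


class SingularityError(MipfLassoError):
    """A linear system or covariance estimate is singular."""


class ConvergenceError(MipfLassoError):
    """An iterative solver failed to reach its tolerance.

    Carries the last residual so callers can decide whether the
    partial answer is usable.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class LeakageError(MipfLassoError):
    """Test-set indices reached a routine that fits parameters."""
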