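"""Exception hierarchy for the sigma-competition model."""


class SigmaCompError(Exception):
    """Base class for all package errors."""


class DomainError(SigmaCompError, ValueError):
    """An argument lies outside the physical domain (negative total, kd <= 0, ...)."""


class UsageError(SigmaCompError, ValueError):
    """The call is structurally invalid (empty species list, missing labels, ...)."""


class ConfigError(SigmaCompError, ValueError):
    """A scenario configuration failed validation or cross-reference resolution."""


class SolverError(SigmaCompError, RuntimeError):
    """A numerical solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, *, residual: float | None = None,
                 iterations: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class InconsistentStateError(SigmaCompError, ValueError):
    """Internally contradictory state (e.g. transcription flux without holoenzymes)."""


def check_nonnegative(**kwargs: float) -> None:
    """Raise :class:`DomainError` naming the first negative argument."""
    for name, value in kwargs.items():
        if value < 0:
            raise DomainError(f"argument {name!r} must be >= 0, got {value!r}")


def check_positive(**kwargs: float) -> None:
    """Raise :class:`DomainError` naming the first non-positive argument."""
    for name, value in kwargs.items():
        if not value > 0:
            raise DomainError(f"argument {name!r} must be > 0, got {value!r}")
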