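"""Exception types shared across the package."""

from __future__ import annotations


class RVSError(Exception):
    """Base class for all package-specific errors."""


class ModelValidationError(RVSError, ValueError):
    """A model parameterization violates a structural invariant."""


class DegenerateModelError(RVSError, ValueError):
    """All selection weights vanish, or a required logarithm argument is zero."""


class OneWayTransitionError(RVSError, ValueError):
    """Directionality requested for a pair whose reverse transition is impossible."""


class SizeCapError(RVSError, ValueError):
    """Composition-space enumeration would exceed the configured state cap."""


class ReducibleChainError(RVSError, RuntimeError):
    """The transition matrix has more than one recurrent class.

    The recurrent classes (lists of state indices) are attached so callers
    can inspect the competing stationary supports.
    """

    def __init__(self, message: str, recurrent_classes: list[list[int]]):
        super().__init__(message)
        self.recurrent_classes = recurrent_classes


class NonConvergenceError(RVSError, RuntimeError):
    """Iterative solver failed to reach tolerance; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class RestrictedRegimeError(RVSError, ValueError):
    """An operation defined only for near-uniform variation probabilities was
    invoked on a model whose per-type variation probabilities are heterogeneous."""
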