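"""Exception hierarchy shared across the toolkit.

All errors derive from :class:`MinigeneError` so callers can catch the
package's failures with a single except clause while still discriminating
the specific condition.
"""


class MinigeneError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MinigeneError, ValueError):
    """Malformed data: bad alphabet, empty sequence, mismatched shapes."""


class InvalidConfigError(MinigeneError, ValueError):
    """Parameter combination that can never be valid (e.g. window <= overlap)."""


class ProvenanceError(MinigeneError, ValueError):
    """Declared source state does not match the actual sequence."""


class RefinementExhausted(MinigeneError):
    """A fragment cannot be split further without dropping below min_length."""


class NoPositiveFragments(MinigeneError):
    """Epitope localization requested but no fragment tested positive."""


class InconsistentEpitopes(MinigeneError):
    """Positive fragments have an empty intersection (likely multiple epitopes)."""


class UnsatisfiableConstraints(MinigeneError):
    """Backtranslation repair loop could not satisfy the sequence constraints."""

    def __init__(self, message: str, stuck_window: tuple[int, int] | None = None):
        super().__init__(message)
        self.stuck_window = stuck_window


class InfeasibleDesignError(MinigeneError, ValueError):
    """Pool design parameters violate a provable feasibility bound."""


class PartialDesignError(MinigeneError):
    """The pool solver ran out of its search budget before completing."""


class DegenerateExperimentError(MinigeneError):
    """Screen statistics undefined (e.g. zero variance across wells)."""


class OffsetTooSmallError(MinigeneError, ValueError):
    """Geometric-mean offset leaves non-positive shifted values."""
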