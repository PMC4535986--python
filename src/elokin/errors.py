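"""Exception hierarchy.

All package-specific failures derive from :class:`ElokinError` so callers can
catch one base class; subclasses distinguish parse problems, invalid model
states and numerical failures.
"""


class ElokinError(Exception):
    """Base class for all elokin errors."""


class ParseError(ElokinError):
    """A table or sequence file could not be parsed; the message names the cell."""


class ValidationError(ElokinError):
    """An in-memory object violates one of its invariants."""


class DegenerateStateError(ElokinError):
    """A reachable transient state has zero total outgoing rate."""


class NoAbsorptionError(ElokinError):
    """No path with positive rate leads from the initial state to absorption."""


class UndefinedFidelityError(ElokinError):
    """Both effective accommodation rates vanish; accommodation probabilities undefined."""


class NonConvergenceError(ElokinError):
    """The self-consistent solver exhausted its sweep budget.

    Carries the residual trace for diagnosis.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals) if residuals is not None else []


class InfeasibleParametersError(ElokinError):
    """The parameter set admits no physical solution (e.g. EF-Tu pool insufficient)."""
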