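"""Exception types shared across the package.

All validation failures raise :class:`ValidationError` (a ``ValueError``)
so callers can catch one type; more specific subclasses carry context.
"""


class ValidationError(ValueError):
    """Input violates a documented precondition or schema."""


class ChronogramError(ValidationError):
    """A tree cannot be used as a chronogram (parse, rooting, branch lengths)."""


class UltrametricityError(ChronogramError):
    """Root-to-tip depths disagree beyond tolerance.

    Attributes
    ----------
    max_deviation : float
        Largest pairwise difference among root-to-tip path lengths (Myr).
    """

    def __init__(self, message: str, max_deviation: float):
        super().__init__(message)
        self.max_deviation = max_deviation


class SimulationError(RuntimeError):
    """A stochastic simulation failed to satisfy its stopping/conditioning rule."""
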