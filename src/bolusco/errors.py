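"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`BoluscoError`
so callers (and the CLI) can separate domain failures from programming bugs.
``ValidationError`` additionally subclasses ``ValueError`` because it signals
malformed user input rather than a runtime failure.
"""


class BoluscoError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(BoluscoError, ValueError):
    """Invalid input: out-of-range parameter, malformed file, bad config."""


class ModelConstructionError(BoluscoError):
    """Compartment topology that breaks flow conservation or volume budget."""


class SolverFailureError(BoluscoError):
    """The ODE integrator produced a non-finite or negative state."""


class PeakNotCapturedError(BoluscoError):
    """The curve maximum sits on the first or last sample (truncated peak).

    ``position`` is ``"start"`` or ``"end"`` -- which edge the maximum hit.
    """

    def __init__(self, message: str, position: str = "end"):
        super().__init__(message)
        self.position = position


class BracketFailureError(BoluscoError):
    """Observed time-to-peak lies outside the simulated bracket.

    Carries the simulated TTP at both bracket endpoints so the caller can
    widen the search or report the mismatch.
    """

    def __init__(self, message: str, ttp_at_lo: float, ttp_at_hi: float):
        super().__init__(message)
        self.ttp_at_lo = ttp_at_lo
        self.ttp_at_hi = ttp_at_hi


class InsufficientDataError(BoluscoError):
    """Too few usable samples for the requested fit or statistic."""


class InvalidFitError(BoluscoError):
    """A fitted curve violates its own constraints (e.g. non-positive AUC)."""


class EmptyCurveError(BoluscoError):
    """Truncation removed every sample of a time-density curve."""


class UndefinedCorrelationError(BoluscoError):
    """Correlation requested on a zero-variance vector."""


class StratificationError(BoluscoError):
    """More strata requested than observations available."""
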