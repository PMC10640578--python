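"""Exception types shared across the package."""

from __future__ import annotations


class ParameterError(ValueError):
    """A parameter is outside its admissible range."""


class EstimationError(RuntimeError):
    """A statistical fit cannot be performed on the given sample."""


class InconsistencyError(RuntimeError):
    """The target waiting-time laws admit no valid joint update.

    Raised when one of the four joint step probabilities of a two-node
    system falls below zero by more than the rounding guard.  Carries
    enough context to report *where* the construction broke down.

    Attributes
    ----------
    time : int or None
        Time step at which the violation occurred.
    unit : object or None
        Identifier of the offending unit (e.g. the trunk edge).
    probabilities : tuple or None
        The (p1, p2, p3, p4) quadruple that contained a negative entry.
    trajectories : tuple or None
        The (x, y) trajectories at the moment of violation, if available.
    """

    def __init__(self, message, *, time=None, unit=None, probabilities=None,
                 trajectories=None):
        super().__init__(message)
        self.time = time
        self.unit = unit
        self.probabilities = probabilities
        self.trajectories = trajectories
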