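"""Exception hierarchy for the matg package."""


class MatgError(Exception):
    """Base class for all matg errors."""


class InvalidAllocationError(MatgError):
    """An allocation is negative or exceeds the available endowment."""


class UnavailableInteractionError(MatgError):
    """A return was requested from a confederate that was not available."""


class ClockError(MatgError):
    """An event was recorded out of round order."""


class RetrievalFailureError(MatgError):
    """Activation requested for a chunk with no encodings."""


class NoExperienceError(MatgError):
    """No stored instances exist for a counterpart; caller must fall back to a prior."""


class AlignmentError(MatgError):
    """Curves or logs do not line up on rounds x counterparts."""


class ConstantSeriesError(MatgError):
    """Pearson correlation is undefined because a series is constant."""


class LogValidationError(MatgError):
    """A game log violates a round-record invariant."""
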