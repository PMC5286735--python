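"""Structured exceptions raised across the package."""


class LcasubError(Exception):
    """Base class for all package errors."""


class CodebookError(LcasubError):
    """Invalid variable declaration or codebook structure."""


class DataValidationError(LcasubError):
    """Data does not conform to its codebook (levels, ranges, missing rows)."""


class DimensionMismatchError(LcasubError):
    """Model and data/codebook disagree on variables or level sets."""


class ClassCollapseError(LcasubError):
    """A latent class lost essentially all posterior weight during an M-step.

    Signals that the current EM run is degenerate; a restart from a different
    seed is advised rather than silently renormalising the empty class.
    """


class ConvergenceWarning(UserWarning):
    """EM did not converge within the iteration budget."""
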