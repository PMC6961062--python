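"""Exception hierarchy for tremorkit.

Every error raised by the library derives from :class:`TremorKitError`, so
callers (and the CLI) can catch one base class. Subclasses mark the contract
that was violated rather than the module that raised them.
"""


class TremorKitError(Exception):
    """Base class for all tremorkit errors."""


class ParseError(TremorKitError):
    """A text recording contains a token that cannot be parsed as a number."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        super().__init__(message)
        self.line = line
        self.column = column


class ChannelSpecError(TremorKitError):
    """A channel specification is inconsistent with the data file."""


class InsufficientDataError(TremorKitError):
    """The signal is too short for the requested operation."""


class NyquistError(TremorKitError):
    """A filter cutoff is at or above the Nyquist frequency."""


class ParameterError(TremorKitError):
    """A numeric parameter is outside its valid range."""


class WindowError(TremorKitError):
    """A segmentation/analysis window does not fit the signal."""


class DegenerateCoherenceError(TremorKitError):
    """Coherence requested with fewer than two segments (estimator is identically 1)."""


class BandError(TremorKitError):
    """A frequency band does not intersect the spectrum's grid."""


class UndefinedICCError(TremorKitError):
    """ICC is undefined because the ratings carry no variance."""


class HarnessError(TremorKitError):
    """An extractor failed inside the agreement-comparison harness."""
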