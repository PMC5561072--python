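"""Exception hierarchy for polydfs.

All errors derive from :class:`PolyDFSError` so callers can catch the
package's failures with a single except clause while still
distinguishing domain errors (bad physical input) from numerical
failures (non-convergence) and pipeline rejections.
"""


class PolyDFSError(Exception):
    """Base class for all polydfs errors."""


class DomainError(PolyDFSError, ValueError):
    """Input outside the physically valid domain of a model."""


class NumericalError(PolyDFSError, RuntimeError):
    """A numerical routine failed to converge or overflowed."""


class OverflowGuardError(NumericalError):
    """An exponential argument exceeded the guard threshold."""


class ExtensionOverflowError(NumericalError):
    """A simulated tether reached full extension without rupturing."""


class FitError(PolyDFSError, RuntimeError):
    """A model fit could not be performed or did not converge."""


class WindowError(PolyDFSError, ValueError):
    """A fit or slope window contains too few samples."""


class EventFlaggedError(PolyDFSError, ValueError):
    """An event failed a per-event quality check (e.g. non-positive slope)."""


class AllEventsFilteredError(PolyDFSError, ValueError):
    """The persistence-length filter removed every event."""


class EmptySpectrumError(PolyDFSError, ValueError):
    """No events were available to build a mean-force spectrum."""
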