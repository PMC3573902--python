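"""Exception hierarchy shared across the pipeline.

All data/validation problems raise :class:`DielgrowError` subclasses so the
CLI can map them onto stable exit codes (0 ok, 1 usage, 2 data, 3 internal).
"""


class DielgrowError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(DielgrowError, ValueError):
    """An input value or data structure violates a documented invariant."""


class StackIOError(DielgrowError, IOError):
    """A stack file could not be read or written."""


class WindowError(DielgrowError):
    """A spatiotemporal analysis window does not fit inside the stack."""


class SegmentationError(DielgrowError):
    """The root (foreground) could not be segmented from a frame."""


class AmbiguityError(DielgrowError):
    """Tip location is ambiguous (e.g. two equally distant skeleton ends)."""

    def __init__(self, message, candidates=()):
        super().__init__(message)
        self.candidates = list(candidates)


class RegistrationError(DielgrowError):
    """Anchor patch could not be registered (textureless or lost)."""


class TrackingLostError(DielgrowError):
    """An advected area of interest degenerated; tracking cannot continue."""


class QualityError(DielgrowError):
    """Too few valid pixels/frames to produce a trustworthy number."""

    def __init__(self, message, n_valid=None):
        super().__init__(message)
        self.n_valid = n_valid
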