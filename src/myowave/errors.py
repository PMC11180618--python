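"""Exception hierarchy for the myowave pipeline.

Every error raised by the package derives from :class:`MyowaveError`, so
callers (and the CLI) can distinguish validation problems (bad inputs,
malformed tables) from processing problems (decode failures, degenerate
geometry) with a single ``except`` clause each.
"""


class MyowaveError(Exception):
    """Base class for all package errors."""


class ValidationError(MyowaveError, ValueError):
    """An input object violates its documented invariants."""


class DecodeError(MyowaveError, IOError):
    """A video file could not be read or produced no frames."""


class VideoFormatError(MyowaveError, ValueError):
    """Frames in a container are inconsistent (size, channels)."""


class BoundsError(MyowaveError, ValueError):
    """A rectangle, column or index falls outside the frame/map."""


class TableFormatError(MyowaveError, ValueError):
    """A CSV table is missing required columns or has bad values."""


class InsufficientFramesError(MyowaveError, ValueError):
    """The stack is too short for the requested temporal kernel."""


class FrameSizeError(MyowaveError, ValueError):
    """A frame or map is smaller than the filter aperture."""


class DegenerateAnnotationError(MyowaveError, ValueError):
    """A wave annotation spans zero frames (slope undefined)."""


class UndersizedSegmentError(MyowaveError, ValueError):
    """A horn segment holds fewer annotated waves than requested."""


class HornExclusionError(MyowaveError, ValueError):
    """A horn fails an inclusion rule (e.g. fewer than three embryos)."""


class GeometryError(MyowaveError, ValueError):
    """Simulated tube geometry does not fit the requested frame."""
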