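"""Exception hierarchy for the m-DC pipeline.

``ConfigError`` maps to exit code 2 on the command line, ``DataError``
(and subclasses) to exit code 3.
"""


class MDCError(Exception):
    """Base class for all package errors."""


class ConfigError(MDCError):
    """Invalid configuration, missing paths, malformed specs."""


class DataError(MDCError):
    """Input data violates a precondition of an analysis stage."""


class GeometryError(DataError):
    """A synthetic contour does not fit the frame or is not star-shaped."""


class NoCellDetectedError(DataError):
    """Segmentation found no usable foreground component in a frame."""


class InsufficientTraceError(DataError):
    """Fewer than three usable frames remain after per-frame QC."""
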