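"""Exception hierarchy for the rowweed pipeline.

Every stage raises a subclass of :class:`RowweedError` so that the CLI can
report failures with a stage name and a nonzero exit status.
"""


class RowweedError(Exception):
    """Base class for all rowweed errors."""


class InvalidArgumentError(RowweedError, ValueError):
    """A parameter is outside its documented range."""


class ConfigurationError(RowweedError, ValueError):
    """The image/config lacks something a stage needs (e.g. a band)."""


class BoundsError(RowweedError, IndexError):
    """A region/frame lies (partly) outside the raster."""


class CalibrationError(RowweedError):
    """Radiometric calibration cannot be performed (bad panel statistics)."""


class DegenerateInputError(RowweedError, ValueError):
    """Input carries no usable signal (e.g. constant values for Otsu)."""


class NoVegetationError(RowweedError):
    """No vegetation objects are available where at least one is required."""


class NoRowsError(RowweedError):
    """No stripe qualifies as a crop row."""
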