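"""Exception hierarchy.

All input-validation failures derive from :class:`ValidationError` so the CLI
can map them to exit code 2; genuine runtime failures use plain exceptions.
"""


class ValidationError(ValueError):
    """Invalid input data or configuration."""


class InvalidMeasurementError(ValidationError):
    """A fluorescence yield violates a physical precondition (e.g. Fm' <= 0)."""


class GridMismatchError(ValidationError):
    """Curves are not on a common time grid."""


class PhaseError(ValidationError):
    """A required measurement phase (dark / illumination / recovery) is missing."""


class UndefinedPhasorError(ValidationError):
    """Phasor coordinates are undefined (zero-area curve)."""


class ExcessiveClippingError(ValidationError):
    """Extreme PCA reconstruction loses too much mass when clipped at zero."""


class DegenerateTriangleError(ValidationError):
    """Phasor triangle vertices are (near-)collinear."""
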