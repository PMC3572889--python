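"""Exception hierarchy for the film-dosimetry pipeline."""


class FilmdoseError(Exception):
    """Base class for all pipeline errors."""


class FormatError(FilmdoseError):
    """An input file or array does not have the expected layout."""


class DimensionError(FilmdoseError):
    """Shapes or pixel spacings of combined maps disagree."""


class BoundsError(FilmdoseError):
    """A region of interest falls outside the image extent."""


class DomainError(FilmdoseError):
    """A value is outside the mathematical domain of an operation
    (non-positive pixel under a log, zero mean under a CV, ...)."""


class CalibrationError(FilmdoseError):
    """The dose-response fit failed to converge or is not monotone."""


class RangeError(FilmdoseError):
    """A dose cannot be represented on the calibration curve's NOD range."""

    def __init__(self, message: str, dose_min: float | None = None,
                 dose_max: float | None = None):
        super().__init__(message)
        self.dose_min = dose_min
        self.dose_max = dose_max


class GeometryError(FilmdoseError):
    """Invalid physical geometry (grid touching the source, no overlap...)."""
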