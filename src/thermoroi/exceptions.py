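"""Exception and warning types shared across the package."""


class ThermoroiError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ThermoroiError):
    """A file or directory does not conform to the expected interchange format."""


class ShapeError(ThermoroiError):
    """Frames in a sequence disagree in shape, or a grid is degenerate."""


class SegmentationError(ThermoroiError):
    """A frame could not be segmented (e.g. no valid pixel in the search window)."""


class FiducialDetectionError(ThermoroiError):
    """The fiducial detector did not find exactly four candidate disks."""

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = candidates if candidates is not None else []


class DegenerateGeometryError(ThermoroiError):
    """Point correspondences are degenerate (collinear / coincident)."""


class UnitError(ThermoroiError):
    """A quantity is outside its plausible physical band, suggesting wrong units."""


class ZeroVarianceError(ThermoroiError):
    """A statistic is undefined because the data have zero variance."""


class TemperatureBandWarning(UserWarning):
    """Temperatures fall outside the configured plausible band."""


class MissingFrameWarning(UserWarning):
    """A frame was skipped (unsegmentable) and excluded from sequence averages."""
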