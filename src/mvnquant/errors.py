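"""Exception hierarchy for mvnquant."""


class MvnQuantError(Exception):
    """Base class for all package errors."""


class DensityInfeasibleError(MvnQuantError):
    """Requested network density cannot be realized in the given domain."""


class InfeasibleCoverageError(MvnQuantError):
    """Requested pericyte coverage exceeds what the vessel surface can host."""


class UnknownPresetError(KeyError, MvnQuantError):
    """Preset name is not in the registry."""


class UnknownMarkerError(KeyError, MvnQuantError):
    """Marker has no registered threshold or border."""


class CalibrationMissingError(MvnQuantError):
    """Image file carries no voxel-size calibration and no sidecar was found."""


class GridMismatchError(MvnQuantError):
    """Operands do not share the same pixel/voxel grid."""


class LayoutInvalidError(MvnQuantError):
    """ROI layout rectangles overlap or exceed image bounds."""


class UndefinedFractionError(MvnQuantError):
    """A fraction is undefined because its denominator region is empty."""


class UndefinedViabilityError(MvnQuantError):
    """Viability is undefined because there are no nuclei."""


class DegenerateHistogramError(MvnQuantError):
    """Multi-Otsu thresholding failed on a (near-)constant image."""


class SeedingFailureError(MvnQuantError):
    """Random-walk segmentation could not derive seeds for both labels."""


class NoVesselError(MvnQuantError):
    """Operation requires a non-empty vessel mask."""


class InvalidContrastError(MvnQuantError):
    """Intravascular tracer intensity does not exceed background."""


class MissingFrameError(MvnQuantError):
    """Requested time point is absent from the perfusion series."""


class ConfigError(MvnQuantError):
    """Pipeline configuration is invalid or incomplete."""
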