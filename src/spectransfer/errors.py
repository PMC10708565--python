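"""Exception hierarchy shared across the package."""


class SpectransferError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpectransferError):
    """A file or header could not be parsed."""


class DimensionError(SpectransferError):
    """Array shapes or band grids are incompatible."""


class CalibrationError(SpectransferError):
    """Reflectance calibration is undefined everywhere."""


class ROIError(SpectransferError):
    """A region of interest is empty or entirely invalid."""


class ParameterError(SpectransferError):
    """An argument is outside its admissible range."""


class DegenerateDataError(SpectransferError):
    """Input data admit no well-defined fit (constant reference, zero rank...)."""


class AlignmentError(SpectransferError):
    """Sample ids cannot be aligned across datasets."""


class MappingError(SpectransferError):
    """A wavelength cannot be mapped onto the band grid."""


class PartitioningError(SpectransferError):
    """A cross-validation fold or split is too small to be usable."""


class DataError(SpectransferError):
    """Non-finite or otherwise unusable numeric input."""
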