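"""Exception hierarchy for the dmnfc pipeline.

Every contract violation raises a distinct, named error so callers can
discriminate failure modes without string matching.
"""


class DmnfcError(Exception):
    """Base class for all dmnfc errors."""


class NotFourDimensionalError(DmnfcError):
    """A BOLD image was expected to be 4-D but is not."""


class NonInvertibleAffineError(DmnfcError):
    """The voxel-to-mm affine of an image is singular."""


class ManifestError(DmnfcError):
    """A cohort manifest table is malformed."""


class MissingColumnError(ManifestError):
    """A required manifest column is absent."""


class UnknownGroupError(ManifestError):
    """A manifest row carries a group label outside the allowed set."""


class NonNumericValueError(ManifestError):
    """A numeric manifest field could not be parsed."""


class MotionFileError(DmnfcError):
    """A motion-parameter text file has the wrong shape."""


class AlreadyDiscardedError(DmnfcError):
    """Initial-volume discarding was requested twice for one series."""


class VolumeCountError(DmnfcError):
    """A volume count argument is inconsistent with the series length."""


class BandSpecError(DmnfcError):
    """A band-pass specification is outside (0, Nyquist) or inverted."""


class RankDeficientDesignError(DmnfcError):
    """A regression design matrix is rank deficient."""

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = columns


class ConstantSeedError(DmnfcError):
    """A seed time series has zero variance."""


class EmptySphereError(DmnfcError):
    """A seed sphere contains no voxel of the grid."""


class GridMismatchError(DmnfcError):
    """Two volumes that must share a grid do not."""


class EmptyMaskError(DmnfcError):
    """A mask that must select at least one voxel is empty."""


class EmptyRoiError(DmnfcError):
    """An ROI is empty (possibly after missing-value removal)."""


class InsufficientSubjectsError(DmnfcError):
    """A group-level statistic requires more subjects than supplied."""


class DegenerateDataError(DmnfcError):
    """Input data are degenerate for the requested statistic."""


class ConfigError(DmnfcError):
    """A configuration block is invalid."""
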