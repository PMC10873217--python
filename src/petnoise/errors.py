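"""Exception hierarchy.

Every failure mode named in the public API contracts maps to one subclass so
callers can catch precisely, and the CLI can translate to exit codes.
"""


class PetNoiseError(Exception):
    """Base class for all petnoise errors."""


class AmbiguousInputError(PetNoiseError):
    """Input path does not resolve to exactly one readable series/volume."""


class InconsistentGeometryError(PetNoiseError):
    """Slice spacing or orientation varies beyond tolerance within a series."""


class MetadataError(PetNoiseError):
    """Metadata required for SUV conversion is missing or invalid."""


class IOErrorPetNoise(PetNoiseError):
    """Report or volume could not be written."""


class NoTissueFoundWarning(UserWarning):
    """Thresholding produced an empty tissue mask."""


class DegenerateBlockError(PetNoiseError):
    """Fewer than two values supplied to a standard-deviation computation."""


class SliceTooSmallError(PetNoiseError):
    """Slice is smaller than a single macro-pixel block."""


class NoNoiseSamplesError(PetNoiseError):
    """No valid macro pixels available to build a noise histogram."""


class VoiOutOfBoundsError(PetNoiseError):
    """Requested VOI cube extends beyond the volume."""


class DegenerateVoiError(PetNoiseError):
    """VOI contains fewer than two voxels."""


class ZeroVarianceError(PetNoiseError):
    """Standardization requested on a constant series."""


class UnpairedInputError(PetNoiseError):
    """Paired test received series of unequal length."""


class UndefinedCorrelationError(PetNoiseError):
    """Correlation undefined (constant input series)."""


class DegenerateLabelsError(PetNoiseError):
    """ROC analysis requires both classes to be present."""


class BadPhantomSpecError(PetNoiseError):
    """Phantom specification violates its invariants."""


class SchemaError(PetNoiseError):
    """Tabular input is missing required columns."""
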