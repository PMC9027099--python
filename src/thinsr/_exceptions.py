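"""Exception hierarchy shared across the pipeline."""


class ThinSRError(Exception):
    """Base class for all package errors."""


class VolumeFormatError(ThinSRError):
    """File is not a readable NIfTI volume."""


class DimensionalityError(VolumeFormatError):
    """Image on disk is not three-dimensional."""


class DegenerateRangeError(ThinSRError):
    """Constant-valued volume cannot be min-max standardized."""


class InsufficientSlicesError(ThinSRError):
    """Volume has too few through-plane slices for the requested operation."""


class SplitError(ThinSRError):
    """Patient-level split cannot be formed."""


class PairingError(ThinSRError):
    """Low-resolution and high-resolution volumes cannot be paired."""


class ConstructionError(ThinSRError):
    """Network configuration is invalid."""


class TrainingError(ThinSRError):
    """Optimization diverged or received unusable data."""
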