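"""Exception hierarchy for the cdcs package."""


class CdcsError(Exception):
    """Base class for all package-specific errors."""


class BcdValidityError(CdcsError, ValueError):
    """A 4-bit nibble holds a value outside the binary-coded-decimal range 0-9."""


class CountRangeError(CdcsError, ValueError):
    """A photon count cannot be represented in the configured bits per channel."""


class DegenerateInputError(CdcsError, ValueError):
    """Input carries no usable signal (e.g. an all-zero count stream)."""


class GridError(CdcsError, ValueError):
    """A delay time does not sit on the sampling grid, or lag grids disagree."""


class InsufficientDataError(CdcsError, ValueError):
    """Too few curves/points for the requested statistic or fit."""


class ModelDomainError(CdcsError, ValueError):
    """Physically inadmissible parameter combination for the diffusion model."""


class FormatError(CdcsError, ValueError):
    """A packed-stream file violates the on-disk format (magic, version, length)."""
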