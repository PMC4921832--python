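"""Exception hierarchy.

All package-specific failures derive from :class:`SpecDemuxError` so callers
can catch one base class at pipeline boundaries (the CLI does exactly that).
"""


class SpecDemuxError(Exception):
    """Base class for all specdemux errors."""


class InvalidGridError(SpecDemuxError, ValueError):
    """A wavelength grid is malformed (non-divisible range, bad spacing...)."""


class GridMismatchError(SpecDemuxError, ValueError):
    """Two spectral objects do not share the same wavelength grid."""


class ChannelMismatchError(SpecDemuxError, ValueError):
    """A measurement's channel count does not match the model's."""


class CharacterizationError(SpecDemuxError, ValueError):
    """Narrowband characterization input is incomplete or inconsistent."""


class SingularMatrixError(SpecDemuxError, ValueError):
    """A correlation matrix is singular; a positive ridge is required."""


class OffGridError(SpecDemuxError, ValueError):
    """A requested wavelength is not a grid point."""


class ModelFormatError(SpecDemuxError, ValueError):
    """A serialized model file is corrupt or has an unknown format."""


class ValidationError(SpecDemuxError, ValueError):
    """A configuration or argument violates its contract."""
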