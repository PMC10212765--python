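"""Exception hierarchy shared by all pipeline stages."""


class IMCSpatialError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(IMCSpatialError):
    """A config value is invalid; the message names the offending field."""


class FormatError(IMCSpatialError):
    """An on-disk file does not satisfy the stage's format contract."""


class ValidationError(IMCSpatialError):
    """In-memory data violates a stage precondition."""


class DegenerateInputError(IMCSpatialError):
    """Too few values, or zero variance, for a statistical fit."""


class SegmentationError(IMCSpatialError):
    """Level-set evolution diverged; advises a parameter change."""
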