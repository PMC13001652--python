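"""Exception hierarchy shared across the package."""


class CapError(Exception):
    """Base class for all package-specific errors."""


class InvalidFaceError(CapError, ValueError):
    """A declared face is malformed (duplicate vertices, negative ids, ...)."""


class CapabilityError(CapError, RuntimeError):
    """The requested computation exceeds a documented size bound or needs an
    optional backend that is not installed."""


class CurationError(CapError, ValueError):
    """A sequence or record violates the curation contract."""


class FormatError(CapError, ValueError):
    """A file does not conform to the expected on-disk format."""


class UndefinedMetricError(CapError, ValueError):
    """A metric is mathematically undefined for the given inputs
    (e.g. Pearson correlation of a constant vector)."""


class ValidationError(CapError, ValueError):
    """Model inputs fail validation (NaNs, shape mismatches, bad config)."""
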