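"""Exception types shared across the package."""


class GMNoduleError(Exception):
    """Base class for all package errors."""


class NoObjectError(GMNoduleError):
    """Raised when a mask contains no foreground object."""


class AmbiguousObjectError(GMNoduleError):
    """Raised when a mask contains more than one connected component."""


class DegenerateContourError(GMNoduleError):
    """Raised for contours with zero area (collinear or too few points)."""


class OutOfBoundsError(GMNoduleError):
    """Raised when a contour does not fit the target canvas."""


class SchemaError(GMNoduleError):
    """Raised when a feature table does not match the expected schema."""


class ConfigError(GMNoduleError):
    """Raised for invalid configuration values."""
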