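"""Typed exceptions raised across the package."""


class AmyquantError(Exception):
    """Base class for all package errors."""


class SlideFormatError(AmyquantError):
    """Raised for unreadable or unsupported slide images (bit depth, channels)."""


class RegionError(AmyquantError):
    """Raised for invalid region annotations (geometry type, self-intersection)."""


class ConfigError(AmyquantError):
    """Raised for invalid configuration values."""


class PlateError(AmyquantError):
    """Raised for malformed plate tables or ill-posed standard layouts."""


class FitError(AmyquantError):
    """Raised when a standard curve cannot be fitted (too few points, degenerate data)."""


class StatsError(AmyquantError):
    """Raised for statistical inputs that violate preconditions (empty groups, constant vectors)."""
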