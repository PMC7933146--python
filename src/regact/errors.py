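"""Exception hierarchy shared across the pipeline stages."""


class RegactError(Exception):
    """Base class for all package-specific errors."""


class SizingError(RegactError, ValueError):
    """A generator was asked for more items than its gene/coordinate budget allows."""


class PlacementError(RegactError, RuntimeError):
    """Rejection sampling of genomic intervals exhausted its retry cap."""


class NormalizationError(RegactError, ValueError):
    """A normalization step received degenerate input (e.g. an all-zero sample)."""


class SignatureError(RegactError, ValueError):
    """None of the requested signature genes are present in the matrix."""


class ValidationError(RegactError, ValueError):
    """A record in an input file failed validation; message carries the line number."""


class ConfigError(RegactError, ValueError):
    """Pipeline configuration is missing a required field or holds an invalid value."""
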