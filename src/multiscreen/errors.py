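"""Shared exception types."""


class MultiscreenError(Exception):
    """Base class for package errors."""


class FormatError(MultiscreenError):
    """Input file is structurally malformed (missing columns, bad header)."""


class ValidationError(MultiscreenError):
    """Input rows violate data invariants (strict mode)."""


class ConfigError(MultiscreenError):
    """Invalid configuration value."""


class EmptyDatasetError(MultiscreenError):
    """Operation requires a non-empty dataset."""
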