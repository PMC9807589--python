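"""Exception hierarchy shared across the package."""


class CanondxError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CanondxError, ValueError):
    """Raised for malformed, non-finite or inconsistent inputs."""


class TrainingError(CanondxError):
    """Raised when a classifier cannot be trained on the supplied data."""


class DegenerateBlockError(TrainingError):
    """A time block has no non-degenerate canonical coefficient."""


class OrderSelectionError(CanondxError):
    """No candidate decomposition order passed the independence test."""


class ParseError(CanondxError):
    """Raised for malformed feature tables or model files."""


class SchemaVersionError(ParseError):
    """Model file schema version does not match this package."""
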