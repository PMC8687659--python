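"""Exception types shared across the package."""


class InfoflowError(Exception):
    """Base class for package errors."""


class ConfigurationError(InfoflowError):
    """Invalid simulation or analysis configuration."""


class FormatError(InfoflowError):
    """Malformed input table (missing columns, bad dialect)."""


class DataError(InfoflowError):
    """Structurally valid input with impossible content."""


class AlignmentError(InfoflowError):
    """Two trajectories cannot be paired (insufficient overlap)."""
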