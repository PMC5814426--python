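"""Exception hierarchy used across the pipeline."""


class EEGSexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EEGSexError):
    """Invalid parameter combination (bad band limits, sampling rates, ...)."""


class MontageError(EEGSexError):
    """Unknown or missing channel label."""


class DataError(EEGSexError):
    """Input data does not satisfy an operation's requirements."""


class FormatError(EEGSexError):
    """Malformed or truncated file."""


class ArchitectureError(EEGSexError):
    """Network specification whose shape arithmetic is infeasible."""
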