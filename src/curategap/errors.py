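"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`InputFileError` → 1 (I/O),
everything else derived from :class:`CurategapError` → 2 (validation /
configuration).
"""


class CurategapError(Exception):
    """Base class for all errors raised by curategap."""


class InputFileError(CurategapError):
    """A file could not be read or written."""


class TSVFormatError(CurategapError):
    """A data row violates the expected tab-separated dialect."""

    def __init__(self, message: str, path=None, line_number=None):
        self.path = path
        self.line_number = line_number
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line_number is not None:
            prefix += f"line {line_number}: "
        super().__init__(prefix + message)


class RecordValidationError(CurategapError):
    """A parsed record violates a domain invariant."""


class ConfigurationError(CurategapError):
    """A configuration value is missing or inconsistent."""
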