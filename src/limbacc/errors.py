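"""Exception hierarchy shared across the package."""


class LimbaccError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LimbaccError):
    """A parameter or configuration value is invalid."""


class FormatError(LimbaccError):
    """A file violates the expected on-disk format.

    Carries the offending path and, where resolvable, the row number so the
    message always names the exact location of the problem.
    """

    def __init__(self, message: str, path=None, row=None):
        loc = ""
        if path is not None:
            loc += f" [file: {path}"
            loc += f", row: {row}]" if row is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.row = row


class ValidationError(LimbaccError):
    """An in-memory value violates a domain contract."""
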