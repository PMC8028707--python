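"""Exception hierarchy shared across the package."""


class CscaError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CscaError):
    """A file does not conform to its expected dialect.

    Carries the offending path and, for row-level problems, the 1-based
    line number.
    """

    def __init__(self, message: str, *, path: str | None = None,
                 line: int | None = None) -> None:
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ConfigError(CscaError):
    """Invalid configuration value or missing required setting."""


class DomainError(CscaError):
    """A statistical quantity violates its domain constraints."""


class SpecError(CscaError):
    """An infeasible synthetic-data specification."""
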