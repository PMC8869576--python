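"""Exception hierarchy. All package errors derive from SomnographError."""


class SomnographError(Exception):
    """Base class for all somnograph errors."""


class InvalidInputError(SomnographError):
    """Input violates a precondition (empty series, bad lengths, bad values)."""


class MalformedInputError(SomnographError):
    """A file or record could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class DegenerateInputError(SomnographError):
    """Input is valid but carries no usable signal (e.g. constant heart rate)."""
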