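"""Exception hierarchy."""


class KinlowError(Exception):
    """Base class for all package errors."""


class InputError(KinlowError, ValueError):
    """Invalid argument or malformed input data."""


class ParseError(InputError):
    """Malformed file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
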