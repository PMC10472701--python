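"""Exception hierarchy shared across the pipeline stages."""


class ClassnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ClassnetError):
    """Invalid configuration; names the offending field. CLI exit code 2."""


class SchemaError(ClassnetError):
    """An input file is missing required columns or has a malformed header."""


class IntegrityError(ClassnetError):
    """Data violates a structural invariant (e.g. cross-classroom edge). CLI exit code 3."""


class DegenerateInputError(ClassnetError):
    """The input has no usable variation (all values identical, too few points)."""


class ParseError(ClassnetError):
    """A UCINET DL file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
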