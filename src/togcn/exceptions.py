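"""Exception hierarchy shared across the pipeline stages.

Exit-code mapping used by the CLI: ParameterError -> 2, FormatError -> 3,
anything else raised inside a stage -> 4.
"""


class TogcnError(Exception):
    """Base class for all package errors."""


class ParameterError(TogcnError, ValueError):
    """An argument or configuration value is outside its documented range."""


class FormatError(TogcnError, ValueError):
    """A file or string does not conform to the expected text format.

    Carries an optional ``line`` (1-based) naming the offending record.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(TogcnError, ValueError):
    """Input data violates a precondition (e.g. non-standard residue)."""


class MissingRecordError(TogcnError, KeyError):
    """A requested gene/chromosome/sample is absent from its source."""


class ConstantProfileError(TogcnError, ValueError):
    """Pearson correlation is undefined because a vector is constant."""
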