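"""Exception hierarchy."""


class FamkitError(Exception):
    """Base class for all famkit errors."""


class SchemaError(FamkitError):
    """A tabular input is missing a required column or field."""


class ParseError(FamkitError):
    """A row or record could not be parsed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SaturationError(FamkitError):
    """A distance is saturated (p >= 1) and cannot be corrected."""


class UndefinedRatioError(FamkitError):
    """Ka/Ks ratio undefined because Ks = 0."""
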