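"""Exception hierarchy shared across the toolkit."""


class Sc3kitError(Exception):
    """Base class for all toolkit errors."""


class GffParseError(Sc3kitError):
    """Raised for malformed GFF3 input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class UnknownChromosomeError(Sc3kitError):
    """A feature or read refers to a chromosome absent from the genome layout."""


class ZeroVarianceCellError(Sc3kitError):
    """A cell has zero variance across genes; Pearson distance is undefined."""
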