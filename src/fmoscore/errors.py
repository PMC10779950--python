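"""Exception hierarchy shared across the package."""


class FMOScoreError(Exception):
    """Base class for all fmoscore-specific errors."""


class ParseError(FMOScoreError):
    """A QM output text could not be parsed.

    Carries the offending line and its 1-based number when known.
    """

    def __init__(self, message: str, line_no: int | None = None, line: str | None = None):
        self.line_no = line_no
        self.line = line
        if line_no is not None:
            message = f"{message} (line {line_no}: {line!r})"
        super().__init__(message)


class SchemaError(FMOScoreError):
    """A tabular input is missing mandatory columns or violates the column contract."""


class MissingTermError(FMOScoreError, KeyError):
    """An energy term required by the requested operation is absent from a record."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        return Exception.__str__(self)


class SingularFitError(FMOScoreError, ValueError):
    """The regression design matrix is rank deficient (e.g. a constant term column)."""


class UndefinedMetricError(FMOScoreError, ValueError):
    """A correlation metric is undefined (zero variance in one of the vectors)."""


class DegenerateInputError(FMOScoreError, ValueError):
    """Input too small or degenerate for the requested estimator."""
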