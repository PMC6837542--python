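"""Exception hierarchy shared across the package."""


class CrisprAttnError(Exception):
    """Base class for all package errors."""


class ValidationError(CrisprAttnError):
    """Invalid input value (bad alphabet, empty input, out-of-range parameter)."""


class AlignmentError(ValidationError):
    """sgRNA and DNA sequences of an aligned pair differ in length."""


class ParseError(CrisprAttnError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(CrisprAttnError):
    """Inconsistent or incomplete model/run configuration."""


class TrainingError(CrisprAttnError):
    """Training diverged or could not proceed (e.g. NaN loss)."""


class SamplingError(CrisprAttnError):
    """Batch sampling impossible (e.g. single-class dataset for oversampling)."""


class LookupError_(CrisprAttnError):
    """Requested identifier absent from a container (e.g. gene not in network)."""
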