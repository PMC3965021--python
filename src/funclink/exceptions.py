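"""Exception hierarchy shared across the toolkit."""


class FunclinkError(Exception):
    """Base class for all toolkit errors."""


class ParseError(FunclinkError):
    """A file could not be parsed (wrong column count, non-numeric score...).

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(FunclinkError, ValueError):
    """Input violates a structural invariant (self-link, duplicate, bad parameter)."""


class CalibrationError(FunclinkError):
    """Raw evidence could not be calibrated against the gold standard."""


class EvaluationError(FunclinkError):
    """A network evaluation could not be carried out on the given inputs."""


class QueryError(FunclinkError):
    """A network-search query references genes absent from the network."""


class GenerationError(FunclinkError):
    """A synthetic-data generator received an unusable configuration."""
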