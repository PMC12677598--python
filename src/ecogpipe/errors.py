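"""Exception hierarchy shared across the pipeline."""


class EcogPipeError(Exception):
    """Base class for all ecogpipe errors."""


class InvalidArgumentError(EcogPipeError, ValueError):
    """An argument violates a documented precondition."""


class SessionIOError(EcogPipeError, IOError):
    """Session container could not be read or written."""


class CorruptFileError(SessionIOError):
    """Session container exists but its contents are damaged or incomplete."""


class SchemaVersionError(SessionIOError):
    """Session container was written with an unsupported schema version."""


class NoOverlapError(EcogPipeError):
    """Neural and kinematic streams share no common time range."""


class AliasingError(InvalidArgumentError):
    """Sampling rate too low for the requested frequency content."""


class SingularFitError(EcogPipeError):
    """A closed-form least-squares fit is rank deficient."""

    def __init__(self, message: str, deficient_dimension: int | None = None):
        super().__init__(message)
        self.deficient_dimension = deficient_dimension


class DegenerateLabelsError(EcogPipeError):
    """Classification labels collapse to a single class."""


class DivergenceError(EcogPipeError):
    """Iterative training produced non-finite loss."""
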