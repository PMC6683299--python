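"""Exception hierarchy."""


class GazeflowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GazeflowError):
    """A file or table does not conform to the expected format."""


class IntegrityError(GazeflowError):
    """Data violates an internal consistency invariant."""


class LayoutValidationError(GazeflowError):
    """A stimulus layout fails validation."""


class ArgumentError(GazeflowError, ValueError):
    """An operation received an invalid argument."""


class InferenceError(GazeflowError):
    """A statistical comparison cannot be computed from the given data."""


class UndefinedTestError(InferenceError):
    """A test statistic is undefined for the given input."""


class GenerationError(GazeflowError):
    """The simulator cannot produce data from the given configuration."""
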