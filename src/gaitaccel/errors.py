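"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`GaitAccelError`
so callers (and the CLI) can catch one base class.
"""


class GaitAccelError(Exception):
    """Base class for all errors raised by gaitaccel."""


class InvalidInputError(GaitAccelError):
    """Non-finite or otherwise invalid numeric input."""


class DegenerateInputError(InvalidInputError):
    """Input that makes the requested quantity undefined (e.g. zero gravity vector)."""


class UndefinedHeadingError(DegenerateInputError):
    """Tilt-compensated horizontal field vanished; compass heading undefined."""


class ConfigurationError(GaitAccelError):
    """Invalid parameter or configuration value."""


class AlignmentError(GaitAccelError):
    """Time series that must be sample-aligned are not."""


class FormatError(GaitAccelError):
    """Malformed input file (missing columns, bad rows, non-uniform sampling)."""


class DetectionError(GaitAccelError):
    """Gait-event detection failed; manual annotation suggested."""


class NumericalError(GaitAccelError):
    """Numerical failure inside the filter (singular/indefinite covariance)."""


class PipelineError(GaitAccelError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
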