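"""Exception hierarchy.

``ValidationError`` marks malformed inputs or configuration (CLI exit code 2);
``StageError`` wraps a failure inside a pipeline stage (CLI exit code 3).
"""


class TTKinError(Exception):
    """Base class for all package errors."""


class ValidationError(TTKinError):
    """Invalid input data, parameters, or configuration."""


class NormalizationError(TTKinError):
    """Spike-in normalization cannot proceed (e.g. no usable spike-in)."""


class KineticsError(TTKinError):
    """Half-life estimation cannot proceed (e.g. missing assay)."""


class StatsError(TTKinError):
    """Resampling / test preconditions violated."""


class StageError(TTKinError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
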