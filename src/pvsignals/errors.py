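"""Exception types raised across the pipeline."""


class PVSignalsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PVSignalsError):
    """A configuration value violates an invariant; names the offending key."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"invalid configuration for {key!r}: {message}")


class DialectIOError(PVSignalsError):
    """A dialect file is missing or unreadable."""


class DegenerateTableError(PVSignalsError):
    """A contingency table has no usable rows/columns for a chi-square test."""


class UndefinedInputError(PVSignalsError):
    """A disproportionality statistic was requested on an empty margin."""


class EmptyGroupError(PVSignalsError):
    """An analysis group contains no reports."""


class DegenerateOutcomeError(PVSignalsError):
    """The regression outcome is constant; no model can be fitted."""


class NonConvergenceError(PVSignalsError):
    """The optimiser failed to converge without detectable separation."""

    def __init__(self, message: str, trace=None):
        self.trace = trace or []
        super().__init__(message)


class PipelineStageError(PVSignalsError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")
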