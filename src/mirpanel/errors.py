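"""Exception hierarchy for the mirpanel pipeline."""


class MirPanelError(Exception):
    """Base class for all mirpanel errors."""


class ConfigurationError(MirPanelError):
    """Invalid configuration value; the message names the offending field."""


class GenerationError(MirPanelError):
    """Synthetic-data generation produced or was given invalid quantities."""


class DegenerateCurveError(MirPanelError):
    """Standard curve cannot be fit (fewer than 2 distinct input levels)."""


class InvalidAssayError(MirPanelError):
    """Standard curve fit is physically invalid (non-negative slope)."""


class SampleQualityError(MirPanelError):
    """Sample failed QC (for example all spike-ins undetected)."""


class InsufficientCandidatesError(MirPanelError):
    """Too few candidate reference miRNAs for a stability computation."""


class InsufficientGroupError(MirPanelError):
    """A sample group is too small for the requested statistic."""


class UndefinedCorrelationError(MirPanelError):
    """Correlation undefined (zero variance in one of the vectors)."""


class ConvergenceError(MirPanelError):
    """Iterative fit did not converge within the iteration cap."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CohortLeakageError(MirPanelError):
    """Held-out cohort samples leaked into a training-phase stage."""


class PipelineStageError(MirPanelError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
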