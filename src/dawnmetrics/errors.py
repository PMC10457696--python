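"""Exception hierarchy for the dawnmetrics pipeline."""


class DawnMetricsError(Exception):
    """Base class for all package errors."""


class ConfigError(DawnMetricsError):
    """Invalid configuration; the message names the offending field."""


class IngestError(DawnMetricsError):
    """Malformed input file; row-level problems cite the line number."""


class NoPairError(DawnMetricsError):
    """No pair of consecutive valid days satisfies the selection rule."""

    def __init__(self, participant_id: str, rule: str):
        self.participant_id = participant_id
        self.rule = rule
        super().__init__(
            f"participant {participant_id!r}: no pair of consecutive valid days "
            f"satisfies pair rule {rule!r}"
        )


class DegenerateDesignError(DawnMetricsError):
    """Model design matrix is singular (e.g. a constant predictor)."""


class ConvergenceError(DawnMetricsError):
    """Model fit did not converge."""


class UndefinedCorrelationError(DawnMetricsError):
    """Correlation undefined because one variable has zero variance."""


class PipelineStageError(DawnMetricsError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")
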