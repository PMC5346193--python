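"""Exception hierarchy shared across the toolkit."""


class FlexTrialError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(FlexTrialError):
    """A design, model or run configuration is invalid."""


class SchemeConstraintError(ConfigurationError):
    """An arm subset violates the one-arm-per-class scheme constraint."""


class UnknownIdError(FlexTrialError):
    """Reference to an arm, factor, level, scheme or class that is not declared."""


class ValidationError(FlexTrialError):
    """Participant-level or file-level data failed validation."""


class StageError(FlexTrialError):
    """A workflow stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
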