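"""Exception hierarchy shared across the package."""


class StepAdviceError(Exception):
    """Base class for all package errors."""


class ValidationError(StepAdviceError):
    """Input data violates a documented invariant."""


class InsufficientDataError(StepAdviceError):
    """A step log has fewer valid days than the configured minimum."""

    def __init__(self, participant_id: str, n_valid: int, required: int):
        self.participant_id = participant_id
        self.n_valid = n_valid
        self.required = required
        super().__init__(
            f"step log '{participant_id}': {n_valid} valid day(s), "
            f"at least {required} required"
        )


class ConfigurationError(StepAdviceError):
    """The message library or run configuration is incomplete."""


class RenderError(StepAdviceError):
    """A message template could not be rendered."""
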