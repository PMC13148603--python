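"""Exception types shared across the pipeline stages."""


class UtiAuditError(Exception):
    """Base class for all package errors."""


class ConfigurationError(UtiAuditError):
    """A config object violates its invariants; message names the field."""


class HarmonizationError(UtiAuditError):
    """A raw urinalysis string cannot be mapped to the unified ordinal scale."""


class InfeasibleThresholdError(UtiAuditError):
    """No candidate decision threshold satisfies the policy constraint."""

    def __init__(self, message: str, violating_groups=None):
        super().__init__(message)
        self.violating_groups = list(violating_groups or [])


class StageError(UtiAuditError):
    """A pipeline stage failed; carries the stage name for provenance."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
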