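"""Exception hierarchy for the mirmycn pipeline."""


class MirMycnError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(MirMycnError, ValueError):
    """Invalid simulation or pipeline configuration."""


class InvalidWellError(MirMycnError, ValueError):
    """Reporter well cannot be normalized (non-positive Renilla reading)."""


class DegenerateDistributionError(MirMycnError, ValueError):
    """Robust z-score undefined: median absolute deviation is zero."""


class MissingBaselineError(MirMycnError, KeyError):
    """miRNA has no usable analog-screen baseline for median centering."""


class StageError(MirMycnError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
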