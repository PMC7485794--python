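"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration value violates an invariant; the message names the field."""


class DegenerateCalibrationError(ValueError):
    """Black-white correction is undefined (dark and white panel DN coincide)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")
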