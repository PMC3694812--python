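"""Exception hierarchy shared across the package."""


class PhosflowError(Exception):
    """Base class for all phosflow errors."""


class ValidationError(PhosflowError):
    """Input violates a documented precondition or invariant."""


class FormatError(PhosflowError):
    """A file could not be parsed into the expected layout."""


class StageError(PhosflowError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
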