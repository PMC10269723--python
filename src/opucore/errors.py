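"""Exception hierarchy shared across the package."""


class OpucoreError(Exception):
    """Base class for all package errors."""


class ConfigError(OpucoreError):
    """A configuration value violates its invariants."""


class InputError(OpucoreError):
    """Malformed or inconsistent input data."""


class DelineationError(OpucoreError):
    """The tree cannot support OPU delineation (e.g. no reference tips)."""


class ClassificationError(OpucoreError):
    """An OPU carries no usable evidence for classification."""


class UnclassifiableError(OpucoreError):
    """A genome cluster carries no usable rank evidence."""


class StageError(OpucoreError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
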