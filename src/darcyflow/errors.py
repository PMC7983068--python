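"""Exception hierarchy shared across the package."""


class DarcyflowError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(DarcyflowError):
    """Image grids or array shapes that are required to match do not."""


class DegenerateInputError(DarcyflowError, ValueError):
    """Input is structurally valid but carries no usable information
    (empty mask, zero AIF peak, zero denominator)."""


class ArgumentError(DarcyflowError, ValueError):
    """A scalar argument violates its contract (out of range, wrong sign)."""


class StageError(DarcyflowError):
    """A pipeline stage failed; carries the stage name for audit."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage:{stage}] {message}")
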