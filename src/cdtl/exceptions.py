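"""Exception hierarchy shared across the package."""


class CDTLError(Exception):
    """Base class for all package errors."""


class ValidationError(CDTLError):
    """Input violates a documented precondition or invariant."""


class DimensionalityError(ValidationError):
    """An image or volume has the wrong number of dimensions."""


class DegenerateInputError(ValidationError):
    """Input is too small for the requested operation (e.g. GLCM offset)."""


class StageError(CDTLError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[stage:{stage}] {original}")
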