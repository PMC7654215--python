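"""Exception and warning types shared across the pipeline."""


class CpnetError(Exception):
    """Base class for all pipeline errors; carries a machine-readable code."""

    code = "error"

    def __init__(self, message, code=None):
        super().__init__(message)
        if code is not None:
            self.code = code


class InputError(CpnetError):
    code = "bad-input"


class DialectError(CpnetError):
    code = "unknown-score-dialect"


class EmptyResultError(CpnetError):
    code = "empty-result"


class DegenerateError(CpnetError):
    code = "degenerate"


class StageError(CpnetError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage, original):
        self.stage = stage
        self.original = original
        self.code = getattr(original, "code", "error")
        super().__init__(f"stage '{stage}' failed: {original}")


class CpnetWarning(UserWarning):
    pass
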