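"""Exception hierarchy shared across the package."""


class MegaxError(Exception):
    """Base class for all package errors."""


class FormatError(MegaxError):
    """A file or table does not conform to its expected dialect."""


class ValidationError(MegaxError):
    """Input values violate a documented invariant."""


class InsufficientStudiesError(ValidationError):
    """Fewer studies than the operation requires (pooling needs k >= 2)."""


class DegenerateEffectError(ValidationError):
    """A per-study effect cannot be computed (too few usable samples)."""


class MulticollinearityError(ValidationError):
    """Regression design is rank-deficient."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(
            "design matrix is rank-deficient; aliased terms: " + ", ".join(self.aliased)
        )


class PipelineStageError(MegaxError):
    """An error raised by a pipeline stage, annotated with the stage name."""

    def __init__(self, stage: str, source: object, cause: Exception):
        self.stage = stage
        self.source = source
        self.__cause__ = cause
        super().__init__(f"stage '{stage}' failed on {source!r}: {cause}")
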