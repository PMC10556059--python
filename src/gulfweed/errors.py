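"""Exception hierarchy shared across the package."""


class GulfweedError(Exception):
    """Base class for package errors."""


class SchemaError(GulfweedError):
    """A required column or field is missing or malformed."""


class EmptyInputError(GulfweedError):
    """An input table or file contained no usable records."""


class DomainError(GulfweedError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class UndefinedRatioError(DomainError):
    """A ratio with a zero denominator was requested as a hard value."""


class NotFittableError(GulfweedError):
    """Too few valid points remain to fit a model."""


class OutOfDomainError(GulfweedError):
    """A query point lies outside a gridded field's coverage."""


class UnitsError(GulfweedError):
    """A variable's declared units are not the expected ones."""


class ConfigError(GulfweedError):
    """An invalid or internally inconsistent run configuration."""


class StageError(GulfweedError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
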