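"""Package-specific exceptions."""


class HemriskError(Exception):
    """Base class for all package errors."""


class UndefinedStatisticError(HemriskError):
    """A diagnostic statistic has a zero denominator."""

    def __init__(self, statistic: str) -> None:
        super().__init__(
            f"{statistic} is undefined: zero denominator in 2x2 table"
        )
        self.statistic = statistic


class EmptyContrastError(HemriskError):
    """No records fall in the groups a comparison includes."""


class SchemaError(HemriskError):
    """Cohort CSV does not match the expected column schema."""


class SpecValidationError(HemriskError):
    """A cohort-generator specification violates its constraints."""
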