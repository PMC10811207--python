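"""Exception hierarchy for input validation and file-format problems."""


class DiimlmError(Exception):
    """Base class for all package errors."""


class ValidationError(DiimlmError, ValueError):
    """Input values violate a documented precondition."""


class FormatError(DiimlmError, ValueError):
    """A table or label does not match the expected layout."""


class MissingFoodError(DiimlmError, KeyError):
    """A reported food is absent from the composition matrix.

    Raised instead of silently dropping the food, since dropped foods
    would bias every downstream nutrient intake and DII score.
    """

    def __init__(self, foods):
        self.foods = sorted(foods)
        super().__init__(
            "foods missing from composition matrix: " + ", ".join(map(str, self.foods))
        )


class ConfigError(DiimlmError, ValueError):
    """A run configuration is incomplete or self-contradictory."""
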