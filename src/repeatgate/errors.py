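"""Exception hierarchy shared across the package.

CLI exit-code mapping: ConfigError (and its subclass ValidationError) -> 2,
InputError -> 3, anything else -> 1.
"""


class RepeatGateError(Exception):
    """Base class for all repeatgate errors."""


class ConfigError(RepeatGateError):
    """A configuration document could not be parsed or is incomplete."""


class ValidationError(ConfigError):
    """A parsed configuration value violates a design invariant."""


class InputError(RepeatGateError):
    """A sequence input file is missing, unreadable, or malformed."""


class LowCoverageError(RepeatGateError):
    """Too few on-target reads to call alleles at a locus."""

    def __init__(self, locus: str, unit: str, support: int, min_support: int):
        self.locus = locus
        self.unit = unit
        self.support = support
        self.min_support = min_support
        super().__init__(
            f"{locus}/{unit}: {support} supporting reads "
            f"(minimum required: {min_support})"
        )
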