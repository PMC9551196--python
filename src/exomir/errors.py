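"""Exception hierarchy shared across the pipeline.

CLI exit codes: SchemaError -> 2, DegenerateStatisticError -> 3, ConfigError -> 4.
"""


class ExomirError(Exception):
    """Base class for all package errors."""


class SchemaError(ExomirError):
    """A table is missing a required column or violates an integrity rule."""


class InputError(ExomirError):
    """Input values violate an operation's preconditions."""


class ConfigError(ExomirError):
    """A configuration field is out of its documented range."""


class DegenerateStatisticError(ExomirError):
    """A statistic is undefined for the given data (e.g. constant values)."""
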