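"""Exception hierarchy shared across the package.

Three families map onto the CLI's distinct exit codes: configuration
problems (bad options, missing files), data validation problems (a file
parsed but its contents violate an invariant), and computation problems
(preconditions of a statistical operation not met).
"""


class DogCnvError(Exception):
    """Base class for all package errors."""


class ConfigError(DogCnvError):
    """Invalid or missing run configuration."""


class SchemaError(DogCnvError):
    """A table is missing a required column or uses an unknown label."""


class ValidationError(DogCnvError):
    """Parsed data violate a domain invariant (range, uniqueness, ...)."""


class InputError(DogCnvError):
    """An operation's precondition on its in-memory inputs is not met."""


class FormatError(DogCnvError):
    """A structured file (newick, VCF, BED) could not be parsed."""
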