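"""Exception hierarchy shared across the toolkit.

Every error raised on a user-facing path derives from :class:`DiskfactError`
so the CLI can map failures onto stable exit codes.
"""


class DiskfactError(Exception):
    """Base class for all toolkit errors."""


class DimensionError(DiskfactError):
    """Shapes or declared dimensions do not match the data."""


class FormatError(DiskfactError):
    """A text or binary matrix file violates the expected layout."""


class ParameterError(DiskfactError):
    """An argument is outside its valid domain (bad k, MAF range, ...)."""


class SymmetryError(DiskfactError):
    """A matrix declared symmetric is not, beyond tolerance."""


class ResourceError(DiskfactError):
    """Predicted memory or disk footprint exceeds what is available."""


class ComparisonError(DiskfactError):
    """Two factorizations cannot be compared (kind or shape mismatch)."""


class ComputationError(DiskfactError):
    """The underlying numerical solver failed to converge or returned an error."""
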