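"""Exception hierarchy shared by all analysis stages."""


class CrowdAffectError(Exception):
    """Base class for all package errors."""


class SchemaError(CrowdAffectError):
    """A table is structurally malformed (missing columns, duplicate keys)."""


class ValidationError(CrowdAffectError):
    """A value violates a domain invariant (e.g. rating outside 1..9)."""


class EmptySelectionError(CrowdAffectError):
    """A filter (dimension/population/picture) selected no records."""


class DegenerateInputError(CrowdAffectError):
    """Too little data for the requested decomposition or statistic."""


class MissingDataError(CrowdAffectError):
    """Missing cells encountered under missing_policy='error'."""


class UndefinedICCError(CrowdAffectError):
    """The ICC denominator is zero (no variance in the matrix)."""


class InsufficientPoolError(CrowdAffectError):
    """A picture's rating pool cannot support the requested subsample size."""


class ConfigurationError(CrowdAffectError):
    """Generator or pipeline configuration is internally inconsistent."""
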