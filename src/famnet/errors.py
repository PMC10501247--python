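"""Exception hierarchy shared across the package."""


class FamnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FamnetError, ValueError):
    """A configuration value or function parameter is out of its domain."""


class InvalidInputError(FamnetError, ValueError):
    """Input data violates a precondition (empty group, too few samples, ...)."""


class UndefinedCorrelationError(FamnetError, ValueError):
    """Pearson correlation requested on a constant or too-short vector."""


class MissingSampleError(FamnetError, KeyError):
    """A cohort sample is absent from a required data matrix."""


class DegenerateSplitError(FamnetError, ValueError):
    """A median split produced an empty group."""


class InconsistentUniverseError(FamnetError, ValueError):
    """Two networks being compared were built over different pair universes."""


class TableParseError(FamnetError, ValueError):
    """A delimited input file violates its schema."""
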