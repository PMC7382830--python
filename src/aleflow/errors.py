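"""Exception hierarchy shared across aleflow modules."""


class AleflowError(Exception):
    """Base class for all aleflow errors."""


class SchemaError(AleflowError):
    """An input table does not match its declared schema."""


class UnresolvedReferenceError(AleflowError):
    """An annotation refers to an id that does not exist."""


class DuplicateIdError(AleflowError):
    """Two annotations share one id within a framework."""


class CoordinateBoundsError(AleflowError):
    """A coordinate falls outside ``[0, genome_length)``."""


class FeatureLookupError(AleflowError, KeyError):
    """A feature id is unknown at the requested annotation scale."""


class ConfigurationError(AleflowError):
    """A scenario or run configuration is invalid or infeasible."""


class DagStructureError(AleflowError):
    """The convergence graph violates acyclicity (corrupt framework)."""
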