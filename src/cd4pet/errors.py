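"""Exception hierarchy for the cd4pet pipeline.

Every error raised by the package derives from :class:`CD4PETError` so
callers can catch pipeline failures with a single except clause while the
subclasses keep the failure modes distinguishable (bad parameters vs. empty
geometry vs. missing data).
"""


class CD4PETError(Exception):
    """Base class for all cd4pet errors."""


class InvalidParameterError(CD4PETError, ValueError):
    """A numeric argument violates its domain (non-positive half-life, ...)."""


class EmptyRegionError(CD4PETError, ValueError):
    """A mask or region contains no voxels/pixels."""


class DegenerateCoreError(EmptyRegionError):
    """Core contraction emptied the region (tumor too small for the grid)."""


class UndefinedRatioError(CD4PETError, ZeroDivisionError):
    """A ratio is requested with a zero denominator and no flag channel."""


class MissingTimepointError(CD4PETError, KeyError):
    """A growth curve lacks a required day."""


class EmptyCohortError(CD4PETError, ValueError):
    """A cohort summary was requested for zero subjects."""


class ConfigurationError(CD4PETError, ValueError):
    """A required configuration value is missing or out of range."""


class AlignmentError(CD4PETError, ValueError):
    """Volume and mask grids do not match."""


class InconsistentCountsError(CD4PETError, ValueError):
    """Cell counts violate a subset relation (e.g. FoxP3+CD4+ > CD4+)."""


class InsufficientSampleError(CD4PETError, ValueError):
    """A statistical comparison was requested with too few observations."""


class UnassignableError(CD4PETError, ValueError):
    """A subject cannot be stratified (undefined core-to-margin ratio)."""
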