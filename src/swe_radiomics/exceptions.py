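"""Exception hierarchy for the pipeline.

Every error raised on a contract violation derives from ``SWERadiomicsError``
so callers can catch the package's failures with one clause; the subclasses
mirror the distinct failure modes of the stages (bad spec, bad data on disk,
infeasible ROI placement, undefined statistic, cohort leakage).
"""


class SWERadiomicsError(Exception):
    """Base class for all errors raised by this package."""


class InvalidSpecError(SWERadiomicsError, ValueError):
    """A cohort / network / pipeline configuration violates its invariants."""


class DataError(SWERadiomicsError, ValueError):
    """Raster data violates a physical invariant (e.g. negative stiffness)."""


class FormatError(SWERadiomicsError, ValueError):
    """On-disk case bundle is malformed (shape mismatch, bad manifest)."""


class NoLesionError(SWERadiomicsError, ValueError):
    """An operation requiring a non-empty lesion mask got an empty one."""


class PlacementError(SWERadiomicsError, ValueError):
    """No admissible circular-ROI center exists under the constraints."""


class UndefinedStatisticError(SWERadiomicsError, ValueError):
    """A statistic is undefined for the given input (zero variance, 0/0...)."""


class DegenerateLabelError(SWERadiomicsError, ValueError):
    """Both classes are required but only one is present."""


class ArchitectureError(SWERadiomicsError, ValueError):
    """Network geometry is infeasible (input too small for the pool stack)."""


class NoSignalError(SWERadiomicsError, ValueError):
    """Feature matrix is constant; no signature can be fitted."""


class LeakageError(SWERadiomicsError, RuntimeError):
    """A validation case id appears in the training cohort."""


class IncompleteRunError(SWERadiomicsError, RuntimeError):
    """A reporting step was asked to read artifacts that were never produced."""
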