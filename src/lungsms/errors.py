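"""Exception and warning hierarchy.

Every error the package raises derives from :class:`LungSMSError`, so callers
can catch one base class at pipeline boundaries.  Warnings derive from
:class:`LungSMSWarning` and never interrupt a computation.
"""


class LungSMSError(Exception):
    """Base class for all errors raised by lungsms."""


class FormatError(LungSMSError):
    """An input file could not be read in any supported format."""


class MetadataError(LungSMSError):
    """Required image metadata (spacing, orientation, ...) is missing."""


class SchemaError(LungSMSError):
    """A tabular or JSON input does not match the expected schema."""


class ModelVersionError(SchemaError):
    """A persisted normative model declares an unknown schema version."""


class CohortRowError(SchemaError):
    """A cohort table row holds an unparseable value; carries the row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class SegmentationError(LungSMSError):
    """Lung segmentation found no plausible lung component."""


class PartitionError(LungSMSError):
    """Regional partitioning is impossible (e.g. too few axial slices)."""


class SamplingError(LungSMSError):
    """A calibration reference ROI is empty or below the minimum voxel count."""


class ReferenceInversionError(LungSMSError):
    """The measured air reference is not darker than the blood reference."""


class DegenerateInputError(LungSMSError):
    """An operation received an empty or otherwise degenerate input."""


class DomainError(LungSMSError):
    """A numeric argument lies outside the physically meaningful domain."""


class FitError(LungSMSError):
    """A regression fit could not be performed (degrees of freedom, ...)."""


class ScopeError(LungSMSError):
    """A regional scope was requested that the data or model does not carry."""


class SyntheticSpecError(LungSMSError):
    """A synthetic phantom/cohort specification is infeasible."""


class LungSMSWarning(UserWarning):
    """Base class for all warnings emitted by lungsms."""


class PlausibilityWarning(LungSMSWarning):
    """A value is outside the clinically plausible range (never blocking)."""


class DegenerateModelWarning(LungSMSWarning):
    """A fit succeeded but is degenerate (zero residual variance, ...)."""
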