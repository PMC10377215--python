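"""Exception hierarchy for the physometry pipeline.

All domain errors derive from :class:`PhysometryError` so callers can catch
one base class; subclasses distinguish the failure modes the pipeline is
contractually required to signal (bad metadata, inconsistent geometry, a
fully fused growth plate, ...).
"""


class PhysometryError(Exception):
    """Base class for all physometry errors."""


class ValidationError(PhysometryError, ValueError):
    """An input violated a documented precondition."""


class MetadataError(PhysometryError):
    """A required DICOM tag or metadata field is missing or malformed."""


class ConsistencyError(PhysometryError):
    """Related inputs disagree (mask/slice shapes, mixed slice geometry)."""


class FusedPlateError(PhysometryError):
    """The growth-plate area is zero: the area/volume ratio is undefined.

    Raised instead of returning infinity when a subject's physis is fully
    fused (no segmented plate pixels on any visible slice).
    """


class UndefinedKappaError(PhysometryError):
    """Cohen's kappa is undefined (expected agreement equals 1)."""


class CompletenessError(PhysometryError):
    """An observer is missing measurements for one or more subjects."""
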