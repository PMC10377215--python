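"""Reading knee DICOM slices and the metadata the morphometry consumes.

The only header information the area/volume formulas need is Pixel Spacing
(tag 0028,0030 -- row/column centre-to-centre distance in mm, whose product
is the single-pixel area), Slice Thickness (0018,0050), the matrix size
(0028,0010 / 0028,0011) and Magnetic Field Strength (0018,0087).  This
module reads those tags, exposes them on :class:`KneeSlice`, and assembles
per-subject studies with a homogeneous-geometry guarantee.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom

from .devices import DeviceProfile
from .errors import ConsistencyError, MetadataError, ValidationError

__all__ = [
    "KneeSlice",
    "SubjectStudy",
    "read_slice",
    "pixel_area",
    "load_subject",
    "read_metadata_table",
]


@dataclass
class KneeSlice:
    """One coronal 2D grayscale slice plus its geometric metadata."""

    pixels: np.ndarray  # 2D grayscale
    pixel_spacing: tuple[float, float]  # (row, col) mm
    slice_thickness: float  # mm
    slice_index: int  # 0-based, contiguous within a subject
    source_path: str = ""
    field_strength: float | None = None  # tesla, if known

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("pixel grid must be a non-empty 2D array")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValidationError("pixel spacings must be > 0")
        if self.slice_thickness <= 0:
            raise ValidationError("slice thickness must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SubjectStudy:
    """A subject's ordered slice stack plus demographics and device."""

    subject_id: str
    age: float  # decimal years at examination
    sex: str  # "F" or "M"
    slices: list[KneeSlice] = field(default_factory=list)
    device: DeviceProfile | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not self.slices:
            raise ValidationError("a subject study needs at least one slice")
        ref = self.slices[0]
        for s in self.slices[1:]:
            if s.pixel_spacing != ref.pixel_spacing:
                raise ConsistencyError(
                    f"mixed pixel spacing within subject {self.subject_id}: "
                    f"{s.pixel_spacing} vs {ref.pixel_spacing}"
                )
            if s.slice_thickness != ref.slice_thickness:
                raise ConsistencyError(
                    f"mixed slice thickness within subject {self.subject_id}: "
                    f"{s.slice_thickness} vs {ref.slice_thickness}"
                )

    @property
    def pixel_spacing(self) -> tuple[float, float]:
        return self.slices[0].pixel_spacing

    @property
    def slice_thickness(self) -> float:
        return self.slices[0].slice_thickness

    @property
    def n_slices(self) -> int:
        return len(self.slices)


def read_slice(path: str | Path) -> KneeSlice:
    """Read one DICOM file into a :class:`KneeSlice`.

    Pixel spacing is returned in DICOM (row, column) order as stored.
    A missing Pixel Spacing or Slice Thickness tag raises
    :class:`MetadataError` naming the tag.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pydicom error classes vary
        raise OSError(f"cannot read DICOM file {path}: {exc}") from exc

    if "PixelSpacing" not in ds:
        raise MetadataError(f"{path}: missing tag [0028:0030] Pixel Spacing")
    if "SliceThickness" not in ds or ds.SliceThickness in (None, ""):
        raise MetadataError(f"{path}: missing tag [0018:0050] Slice Thickness")

    spacing = tuple(float(v) for v in ds.PixelSpacing)
    field_strength = None
    if "MagneticFieldStrength" in ds and ds.MagneticFieldStrength not in (None, ""):
        field_strength = float(ds.MagneticFieldStrength)

    index = int(ds.InstanceNumber) - 1 if "InstanceNumber" in ds else 0
    return KneeSlice(
        pixels=ds.pixel_array,
        pixel_spacing=spacing,
        slice_thickness=float(ds.SliceThickness),
        slice_index=index,
        source_path=str(path),
        field_strength=field_strength,
    )


def pixel_area(knee_slice: KneeSlice) -> float:
    """Single-pixel area in mm^2: row spacing x column spacing.

    This is the per-pixel factor every mask area is multiplied by; it is a
    pure function of the header geometry, never of image content.
    """
    r, c = knee_slice.pixel_spacing
    return r * c


def load_subject(directory: str | Path, metadata_record: dict) -> SubjectStudy:
    """Load all DICOM slices of one subject from ``directory``.

    ``metadata_record`` must provide ``subject_id``, ``age`` (decimal years,
    or ``birth_date``/``exam_date`` ISO strings), ``sex``, and optionally a
    ``device`` :class:`DeviceProfile`.  Slices are ordered by slice index
    (Instance Number when present, else filename order) and must be
    contiguous and geometrically homogeneous.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.dcm"))
    if not paths:
        raise OSError(f"no DICOM files (*.dcm) found in {directory}")

    slices = [read_slice(p) for p in paths]
    slices.sort(key=lambda s: (s.slice_index, s.source_path))
    indices = [s.slice_index for s in slices]
    if indices != list(range(indices[0], indices[0] + len(indices))):
        raise ConsistencyError(
            f"slice indices not contiguous in {directory}: {indices}"
        )
    for i, s in enumerate(slices):
        s.slice_index = i  # rebase to 0

    age = _resolve_age(metadata_record)
    device = metadata_record.get("device")
    if not isinstance(device, DeviceProfile):
        device = None  # CSV rows carry only the device name; geometry
        # and field strength come from the DICOM headers instead
    return SubjectStudy(
        subject_id=str(metadata_record["subject_id"]),
        age=age,
        sex=str(metadata_record["sex"]),
        slices=slices,
        device=device,
    )


def _resolve_age(record: dict) -> float:
    """Decimal age in years: exam date minus birth date when dates are
    given (days / 365.25), else the ``age`` field taken as-is."""
    if record.get("birth_date") and record.get("exam_date"):
        from datetime import date

        birth = date.fromisoformat(str(record["birth_date"]))
        exam = date.fromisoformat(str(record["exam_date"]))
        days = (exam - birth).days
        if days <= 0:
            raise ValidationError("exam date must be after birth date")
        return days / 365.25
    if "age" not in record or record["age"] in (None, ""):
        raise MetadataError("metadata record lacks 'age' and birth/exam dates")
    return float(record["age"])


def read_metadata_table(path: str | Path) -> list[dict]:
    """Read a subject metadata CSV (subject_id, age or birth/exam dates,
    sex, device name) into a list of records."""
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
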