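"""MRI device profiles.

A :class:`DeviceProfile` carries exactly the acquisition geometry the
morphometry consumes: pixel spacing (row, col) in mm, image matrix, slice
thickness in mm, and the static magnetic field strength in tesla.

Three scanner presets model the clinical mix this pipeline emulates: a 3 T
scanner at 320x320, a 1.5 T scanner at 512x512 and a 1 T scanner at 288x288,
each with a realistic in-plane resolution range and 3-4 mm slices.  The
default cohort mix is 11 : 30 : 9 across the three scanners.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class DeviceProfile:
    """Acquisition geometry of one MRI scanner configuration."""

    name: str
    field_strength: float  # tesla
    pixel_spacing: tuple[float, float]  # (row, col) mm
    matrix: tuple[int, int]  # (rows, cols) pixels
    slice_thickness: float  # mm

    def __post_init__(self) -> None:
        if self.field_strength <= 0:
            raise ValidationError("field_strength must be > 0")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValidationError("pixel spacings must be > 0")
        if any(m < 64 for m in self.matrix):
            raise ValidationError("matrix dimensions must be >= 64")
        if self.slice_thickness <= 0:
            raise ValidationError("slice_thickness must be > 0")

    @property
    def pixel_area(self) -> float:
        """Single-pixel area in mm^2 (row spacing x column spacing)."""
        return self.pixel_spacing[0] * self.pixel_spacing[1]


@dataclass(frozen=True)
class ScannerPreset:
    """A scanner family: fixed field strength and matrix, a pixel-spacing
    range and a set of admissible slice thicknesses to draw per subject."""

    name: str
    field_strength: float
    matrix: tuple[int, int]
    spacing_range: tuple[float, float]  # mm, uniform per subject
    thickness_choices: tuple[float, ...]  # mm

    def realize(self, spacing: float, thickness: float) -> DeviceProfile:
        return DeviceProfile(
            name=self.name,
            field_strength=self.field_strength,
            pixel_spacing=(spacing, spacing),
            matrix=self.matrix,
            slice_thickness=thickness,
        )


SCANNER_3T = ScannerPreset("scanner_3T", 3.0, (320, 320), (0.484, 0.500), (3.0, 4.0))
SCANNER_1_5T = ScannerPreset("scanner_1.5T", 1.5, (512, 512), (0.273, 0.446), (3.0, 4.0))
SCANNER_1T = ScannerPreset("scanner_1T", 1.0, (288, 288), (0.484, 0.625), (3.0, 4.0))

#: Default cohort device mix (counts 11 : 30 : 9 out of 50).
DEFAULT_DEVICE_MIX: dict[ScannerPreset, float] = {
    SCANNER_3T: 11 / 50,
    SCANNER_1_5T: 30 / 50,
    SCANNER_1T: 9 / 50,
}
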