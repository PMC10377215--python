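"""Seeded synthetic knee phantoms with an age-dependent growth plate.

The generator stands in for patient data: each phantom is a stack of
coronal "T2-like" slices showing a stylised distal femur — bright bone
(union of a shaft rectangle and two condylar ellipses, drawn in physical
millimetre coordinates centred in the field of view) crossed by a dark
horizontal growth-plate band whose thickness shrinks linearly with age,

    t(age) = max(t_min, t0 - k * age),

with defaults t0 = 4 mm, k = 0.18 mm/yr, t_min = 0.8 mm.  The band has a
gently wavy boundary (sinusoid, per-slice random phase) so mask boundaries
are not axis-aligned.  Because the anatomy lives in millimetres, the same
phantom rendered on scanners with different pixel spacing yields the same
physical areas up to discretisation — the property the area-ratio biomarker
relies on.

Ground-truth femur-below-plate and plate masks are produced from the exact
same boolean geometry as the rendered intensities, so a noise-free phantom
thresholded between the plate and bone intensities recovers the plate mask
pixel for pixel.

Intensities: soft tissue 140, bone 200, plate 40 on an 8-bit-like scale;
additive Gaussian noise (default sd 5) is applied after the geometry is
fixed, so the same seed yields the same anatomy at any noise level.  DICOM
output rescales to 12 bits (x16).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize

import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .devices import (
    DEFAULT_DEVICE_MIX,
    DeviceProfile,
    ScannerPreset,
)
from .dicom_io import KneeSlice, SubjectStudy
from .errors import ValidationError
from .segmentation import SegmentationResult

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "plate_thickness",
    "generate_subject",
    "generate_cohort",
    "simulate_observer_masks",
    "write_cohort_dicom",
    "TISSUE_INTENSITY",
    "BONE_INTENSITY",
    "PLATE_INTENSITY",
    "DICOM_RESCALE",
]

# Intensity model (8-bit-like scale).  The femur is embedded in
# mid-intensity soft tissue, as in a real coronal knee image, so the dark
# plate band is the unique low-intensity class in any central ROI.
TISSUE_INTENSITY = 140
BONE_INTENSITY = 200
PLATE_INTENSITY = 40
DICOM_RESCALE = 16  # 8-bit-like -> 12-bit on DICOM write

# Femur geometry in millimetres; y runs downward, origin at image centre.
_SHAFT_HALF_WIDTH = 50.0
_BONE_TOP = -60.0
_SHAFT_BOTTOM = 48.0
_CONDYLE_X = 28.0
_CONDYLE_Y = 30.0
_CONDYLE_A = 28.0  # lateral semi-axis
_CONDYLE_B = 25.0  # vertical semi-axis
_PLATE_CENTER_Y = 15.0
_WAVE_AMPLITUDE = 1.5  # mm
_WAVE_LENGTH = 40.0  # mm
# Lateral shrink of the silhouette toward the anterior/posterior slices.
_SLICE_SCALE_DROP = 0.06

# (t0 mm, k mm/yr, t_min mm); t_min keeps the band at or above one pixel
# for the coarsest supported spacing (0.625 mm), i.e. always resolvable.
_DEFAULT_PLATE_MODEL = (4.0, 0.18, 0.8)
DEFAULT_NOISE_SD = 5.0


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to render one synthetic subject."""

    age: float
    sex: str
    device: DeviceProfile
    n_slices: int = 7
    plate_thickness_model: tuple[float, float, float] = _DEFAULT_PLATE_MODEL
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not (5.0 < self.age < 40.0):
            raise ValidationError(f"age {self.age} outside the supported (5, 40) range")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")
        t0, k, t_min = self.plate_thickness_model
        if t_min <= 0:
            raise ValidationError("t_min must be > 0: the synthetic plate never fully fuses")
        if k < 0 or t0 <= 0:
            raise ValidationError("plate thickness model needs t0 > 0 and k >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Per-slice truth masks and the noiseless biomarker value."""

    femur_masks: list[np.ndarray]
    plate_masks: list[np.ndarray]
    nominal_ari: float

    def __post_init__(self) -> None:
        if len(self.femur_masks) != len(self.plate_masks):
            raise ValidationError("one mask pair per slice required")
        for f, p in zip(self.femur_masks, self.plate_masks):
            if np.logical_and(f, p).any():
                raise ValidationError("plate and femur truth masks must be disjoint")


def plate_thickness(age: float, model: tuple[float, float, float] = _DEFAULT_PLATE_MODEL) -> float:
    """Growth-plate thickness in mm at a given age: max(t_min, t0 - k*age)."""
    t0, k, t_min = model
    return max(t_min, t0 - k * age)


def _slice_geometry(
    device: DeviceProfile, thickness: float, scale: float, phase: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (silhouette, plate, femur-below-plate) grids for one slice."""
    rows, cols = device.matrix
    row_sp, col_sp = device.pixel_spacing
    y = (np.arange(rows) - (rows - 1) / 2.0) * row_sp
    x = (np.arange(cols) - (cols - 1) / 2.0) * col_sp
    xg, yg = np.meshgrid(x, y)
    xs = xg / scale

    shaft = (
        (np.abs(xs) <= _SHAFT_HALF_WIDTH)
        & (yg >= _BONE_TOP)
        & (yg <= _SHAFT_BOTTOM)
    )
    left = ((xs + _CONDYLE_X) / _CONDYLE_A) ** 2 + (
        (yg - _CONDYLE_Y) / _CONDYLE_B
    ) ** 2 <= 1.0
    right = ((xs - _CONDYLE_X) / _CONDYLE_A) ** 2 + (
        (yg - _CONDYLE_Y) / _CONDYLE_B
    ) ** 2 <= 1.0
    silhouette = shaft | left | right

    wave = _WAVE_AMPLITUDE * np.sin(2.0 * math.pi * xg / _WAVE_LENGTH + phase)
    top = _PLATE_CENTER_Y - thickness / 2.0 + wave
    bottom = _PLATE_CENTER_Y + thickness / 2.0 + wave
    plate = silhouette & (yg >= top) & (yg < bottom)
    femur = silhouette & (yg >= bottom)
    return silhouette, plate, femur


def _slice_scales(n_slices: int) -> np.ndarray:
    """Parabolic lateral-size profile: largest at the central slice."""
    if n_slices == 1:
        return np.array([1.0])
    centre = (n_slices - 1) / 2.0
    rel = (np.arange(n_slices) - centre) / centre
    return 1.0 - _SLICE_SCALE_DROP * rel**2


def generate_subject(spec: PhantomSpec) -> tuple[SubjectStudy, GroundTruth]:
    """Render one phantom subject plus its ground truth.

    The same spec (including seed) always yields bit-identical pixels and
    masks; geometry is drawn before noise so noise_sd only changes the
    noise, never the anatomy.
    """
    rng = np.random.default_rng(spec.seed)
    thickness = plate_thickness(spec.age, spec.plate_thickness_model)
    scales = _slice_scales(spec.n_slices)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=spec.n_slices)

    slices: list[KneeSlice] = []
    femur_masks: list[np.ndarray] = []
    plate_masks: list[np.ndarray] = []
    femur_px = 0
    plate_px = 0
    for i in range(spec.n_slices):
        silhouette, plate, femur = _slice_geometry(
            spec.device, thickness, float(scales[i]), float(phases[i])
        )
        img = np.full(silhouette.shape, float(TISSUE_INTENSITY))
        img[silhouette] = BONE_INTENSITY
        img[plate] = PLATE_INTENSITY
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        slices.append(
            KneeSlice(
                pixels=pixels,
                pixel_spacing=spec.device.pixel_spacing,
                slice_thickness=spec.device.slice_thickness,
                slice_index=i,
                field_strength=spec.device.field_strength,
            )
        )
        femur_masks.append(femur)
        plate_masks.append(plate)
        femur_px += int(femur.sum())
        plate_px += int(plate.sum())

    if plate_px == 0:
        raise ValidationError("degenerate phantom: plate not sampled on any slice")
    # Pixel area cancels in the ratio of same-device sums.
    nominal_ari = femur_px / plate_px

    study = SubjectStudy(
        subject_id=f"synthetic-{spec.seed}",
        age=spec.age,
        sex=spec.sex,
        slices=slices,
        device=spec.device,
    )
    truth = GroundTruth(femur_masks, plate_masks, nominal_ari)
    return study, truth


def generate_cohort(
    n_subjects: int,
    age_range: tuple[float, float] = (10.0, 26.0),
    device_mix: dict[ScannerPreset, float] | None = None,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    vary_slices: bool = True,
) -> list[tuple[SubjectStudy, GroundTruth]]:
    """Generate a cohort of phantoms.

    Ages are uniform on ``age_range``; sexes are balanced (F first); each
    subject's scanner is drawn from ``device_mix`` (default 3 T : 1.5 T :
    1 T = 11 : 30 : 9) with per-subject pixel spacing drawn from the
    scanner's resolution range and slice thickness from {3, 4} mm.  With
    ``vary_slices`` the per-subject slice count is drawn from 5-9 centred
    on 7, mirroring a realistic spread of usable coronal slices.
    """
    if n_subjects < 2:
        raise ValidationError("n_subjects must be >= 2")
    lo, hi = age_range
    if not (5.0 < lo < hi < 40.0):
        raise ValidationError(f"degenerate or out-of-range age_range {age_range}")
    if device_mix is None:
        device_mix = DEFAULT_DEVICE_MIX
    presets = list(device_mix.keys())
    weights = np.asarray([device_mix[p] for p in presets], dtype=float)
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, size=n_subjects)
    n_female = (n_subjects + 1) // 2
    sexes = ["F"] * n_female + ["M"] * (n_subjects - n_female)
    device_idx = rng.choice(len(presets), size=n_subjects, p=weights)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)

    cohort = []
    for i in range(n_subjects):
        preset = presets[device_idx[i]]
        spacing = float(rng.uniform(*preset.spacing_range))
        thickness = float(rng.choice(preset.thickness_choices))
        n_slices = (
            int(rng.choice([5, 6, 7, 8, 9], p=[0.05, 0.25, 0.4, 0.25, 0.05]))
            if vary_slices
            else 7
        )
        device = preset.realize(spacing, thickness)
        spec = PhantomSpec(
            age=float(ages[i]),
            sex=sexes[i],
            device=device,
            n_slices=n_slices,
            noise_sd=noise_sd,
            seed=int(subject_seeds[i]),
        )
        study, truth = generate_subject(spec)
        study.subject_id = f"S{i + 1:03d}"
        cohort.append((study, truth))
    return cohort


def _perturb_mask(mask: np.ndarray, magnitude: float, rng: np.random.Generator) -> np.ndarray:
    """Shift a mask boundary by a smooth random field of at most ``magnitude`` px.

    The signed pixel distance to the boundary is compared against a smooth
    random surface (bilinear upsampling of an 8x8 uniform(-m, m) grid), so
    different stretches of the boundary are dilated or eroded independently
    while magnitude stays bounded.  magnitude = 0 reproduces the mask.
    """
    if magnitude == 0:
        return mask.copy()
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    signed = outside - inside  # < 0 inside, > 0 outside
    coarse = rng.uniform(-magnitude, magnitude, size=(8, 8))
    surface = resize(coarse, mask.shape, order=1, mode="edge", anti_aliasing=False)
    return signed < surface


def simulate_observer_masks(
    truth: GroundTruth,
    perturbation: float,
    seed: int,
    n_observers: int = 3,
) -> list[SegmentationResult]:
    """Simulate observers re-drawing the manual femur masks.

    Each observer's femur mask per slice is the truth mask with a random
    boundary dilation/erosion of magnitude at most ``perturbation`` pixels;
    the plate masks are passed through unchanged (the plate step is
    algorithmic, hence observer-independent).  perturbation = 0 reproduces
    the truth exactly for every observer.
    """
    if perturbation < 0:
        raise ValidationError("perturbation must be >= 0")
    rng = np.random.default_rng(seed)
    results = []
    for o in range(n_observers):
        femur = [_perturb_mask(m, perturbation, rng) for m in truth.femur_masks]
        plate = [m.copy() for m in truth.plate_masks]
        results.append(
            SegmentationResult(
                observer_id=f"Obs{o + 1}", femur_masks=femur, plate_masks=plate
            )
        )
    return results


# --------------------------------------------------------------------------
# DICOM serialisation

_UID_ROOT = "1.2.826.0.1.3680043.10.511"


def _make_dataset(
    study: SubjectStudy, knee_slice: KneeSlice, subject_no: int, slice_no: int
) -> FileDataset:
    device = study.device
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    meta.MediaStorageSOPInstanceUID = f"{_UID_ROOT}.{subject_no}.{slice_no}.1"
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = f"{_UID_ROOT}.0.1"

    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = f"{_UID_ROOT}.{subject_no}"
    ds.SeriesInstanceUID = f"{_UID_ROOT}.{subject_no}.0"
    ds.Modality = "MR"
    ds.PatientID = study.subject_id
    ds.PatientSex = study.sex
    ds.InstanceNumber = slice_no

    rows, cols = knee_slice.pixels.shape
    ds.Rows = rows
    ds.Columns = cols
    ds.PixelSpacing = [f"{knee_slice.pixel_spacing[0]:.6f}", f"{knee_slice.pixel_spacing[1]:.6f}"]
    ds.SliceThickness = f"{knee_slice.slice_thickness:g}"
    if device is not None:
        ds.MagneticFieldStrength = f"{device.field_strength:g}"
    elif knee_slice.field_strength is not None:
        ds.MagneticFieldStrength = f"{knee_slice.field_strength:g}"

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 12
    ds.HighBit = 11
    ds.PixelRepresentation = 0
    payload = (knee_slice.pixels.astype(np.uint16) * DICOM_RESCALE).astype("<u2")
    ds.PixelData = payload.tobytes()
    return ds


def write_cohort_dicom(
    cohort: list[tuple[SubjectStudy, GroundTruth]], directory: str | Path
) -> dict[str, list[str]]:
    """Write one Explicit-VR-Little-Endian DICOM file per slice.

    Returns a manifest mapping subject_id -> ordered list of file paths.
    UIDs are derived from subject/slice indices, so rewriting the same
    cohort produces byte-identical files.  An empty cohort yields an empty
    manifest and writes nothing.
    """
    directory = Path(directory)
    manifest: dict[str, list[str]] = {}
    for si, (study, _truth) in enumerate(cohort, start=1):
        subject_dir = directory / study.subject_id
        subject_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for knee_slice in study.slices:
            ds = _make_dataset(study, knee_slice, si, knee_slice.slice_index + 1)
            path = subject_dir / f"slice_{knee_slice.slice_index:02d}.dcm"
            try:
                ds.save_as(path, enforce_file_format=True)
            except OSError as exc:
                raise OSError(f"failed to write DICOM file {path}: {exc}") from exc
            paths.append(str(path))
        manifest[study.subject_id] = paths
    return manifest


def write_cohort_metadata(
    cohort: list[tuple[SubjectStudy, GroundTruth]], path: str | Path
) -> None:
    """Write the subject metadata table (CSV) for a generated cohort."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "age", "sex", "device", "field_strength"])
        for study, _ in cohort:
            writer.writerow(
                [
                    study.subject_id,
                    f"{study.age:.4f}",
                    study.sex,
                    study.device.name if study.device else "",
                    study.device.field_strength if study.device else "",
                ]
            )


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
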