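"""Two-step growth-plate segmentation.

Step one is manual: a femur-below-plate mask drawn by an observer arrives
as a lossless image file (or a simulated observer mask).  Step two is
semi-automatic: crop a fixed region of interest around the physis,
optionally median-filter it, keep the pixels whose intensity falls in a
[Tmin, Tmax] range (the dark plate band against bright bone), clean the
binary result morphologically, and re-embed it in full-frame coordinates.

The threshold range can be fixed or derived from the ROI histogram with
Otsu's method: the plate class is selected as [ROI minimum, alpha * T_otsu]
with alpha = 0.6 by default, which lands between the dark-band and bone
modes for any strictly bimodal ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import closing, erosion, disk

from .dicom_io import KneeSlice
from .errors import ConsistencyError, ValidationError

__all__ = [
    "ThresholdSpec",
    "BoundingBox",
    "RefineParams",
    "SegmentationResult",
    "crop_roi",
    "threshold_segment",
    "refine_mask",
    "auto_threshold",
    "segment_growth_plate",
    "load_femur_mask",
    "is_plate_visible",
    "outline_overlay",
    "default_roi_box",
    "DEFAULT_ROI_WINDOW_MM",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Inclusive intensity range [t_min, t_max] preserved by thresholding."""

    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise ValidationError(f"t_min {self.t_min} > t_max {self.t_max}")


@dataclass(frozen=True)
class BoundingBox:
    """0-based, half-open rectangular window in (row, col) coordinates."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValidationError("bounding box must be at least 1x1")
        if self.top < 0 or self.left < 0:
            raise ValidationError("bounding box must start inside the image")

    def validate_within(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.top + self.height > rows or self.left + self.width > cols:
            raise ValidationError(
                f"bounding box {self} exceeds image bounds {shape}"
            )

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.top, self.top + self.height),
            slice(self.left, self.left + self.width),
        )


@dataclass(frozen=True)
class RefineParams:
    """Binary-mask clean-up settings.

    median applies a 3x3 median filter to the ROI *before* thresholding;
    the remaining steps run on the thresholded mask in order: closing with
    an elliptical (disk) element of radius close_radius, removal of
    connected components below min_component pixels, and optionally keeping
    only the largest component.
    """

    median: bool = False
    close_radius: int = 1
    min_component: int = 20
    keep_largest: bool = False


@dataclass
class SegmentationResult:
    """Per-slice binary masks for one observer."""

    observer_id: str
    femur_masks: list[np.ndarray]
    plate_masks: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.femur_masks) != len(self.plate_masks):
            raise ConsistencyError("femur and plate mask lists differ in length")
        for f, p in zip(self.femur_masks, self.plate_masks):
            if f.shape != p.shape:
                raise ConsistencyError("femur/plate mask shapes differ")

    def enforce_disjoint(self) -> None:
        """Resolve femur/plate overlap in favour of the plate.

        The two areas enter the ratio as disjoint regions, so any pixel
        claimed by both after refinement is removed from the femur mask.
        """
        self.femur_masks = [
            np.logical_and(f, np.logical_not(p))
            for f, p in zip(self.femur_masks, self.plate_masks)
        ]


def _as_image(image: np.ndarray | KneeSlice) -> np.ndarray:
    if isinstance(image, KneeSlice):
        return image.pixels
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError("expected a non-empty 2D image")
    return arr


def crop_roi(image: np.ndarray | KneeSlice, box: BoundingBox) -> np.ndarray:
    """Extract the region-of-interest patch (a copy) defined by ``box``."""
    arr = _as_image(image)
    box.validate_within(arr.shape)
    r, c = box.slices
    return arr[r, c].copy()


def threshold_segment(image: np.ndarray | KneeSlice, spec: ThresholdSpec) -> np.ndarray:
    """Range thresholding: mask = 1 where t_min <= I(x, y) <= t_max.

    Both ends of the range are inclusive; everything outside is discarded.
    """
    arr = _as_image(image)
    return (arr >= spec.t_min) & (arr <= spec.t_max)


def auto_threshold(roi: np.ndarray, otsu_fraction: float = 0.6) -> ThresholdSpec:
    """Derive a range that selects the darkest class of the ROI histogram.

    A knee ROI holds three intensity classes — dark plate band, mid soft
    tissue, bright bone — so the upper bound is the lowest of the two
    three-class Otsu splits, which tracks the plate/tissue boundary
    regardless of the tissue/bone mix.  ROIs with fewer than three distinct
    grey levels fall back to ``otsu_fraction`` times the two-class Otsu
    split.  The lower bound is the ROI minimum.  Raises on a constant ROI,
    where no split exists.
    """
    arr = np.asarray(roi, dtype=np.float64)
    n_distinct = np.unique(arr).size if arr.size else 0
    if n_distinct < 2:
        raise ValidationError("auto threshold needs an ROI with >= 2 distinct intensities")
    t_min = float(arr.min())
    if n_distinct >= 3:
        t_max = float(threshold_multiotsu(arr, classes=3)[0])
    else:
        t_max = max(t_min, otsu_fraction * float(threshold_otsu(arr)))
    return ThresholdSpec(t_min, t_max)


def refine_mask(mask: np.ndarray, params: RefineParams = RefineParams()) -> np.ndarray:
    """Morphological clean-up of a binary mask (closing, size filter,
    optional keep-largest).  Output is boolean and never exceeds the input
    domain; an empty mask stays empty."""
    out = np.asarray(mask, dtype=bool)
    if params.close_radius > 0 and out.any():
        out = closing(out, disk(params.close_radius)).astype(bool)
    eight = np.ones((3, 3), dtype=bool)  # 8-connectivity for components
    if params.min_component > 0 and out.any():
        labels, n = ndimage.label(out, structure=eight)
        if n:
            sizes = ndimage.sum_labels(out, labels, index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= params.min_component) + 1
            out = np.isin(labels, keep)
    if params.keep_largest and out.any():
        labels, n = ndimage.label(out, structure=eight)
        sizes = ndimage.sum_labels(out, labels, index=np.arange(1, n + 1))
        out = labels == (int(np.argmax(sizes)) + 1)
    return out


def segment_growth_plate(
    knee_slice: KneeSlice | np.ndarray,
    box: BoundingBox,
    spec: ThresholdSpec | None = None,
    refine: RefineParams = RefineParams(),
    otsu_fraction: float = 0.6,
) -> np.ndarray:
    """Full semi-automatic plate segmentation for one slice.

    crop -> (optional 3x3 median) -> range threshold (``spec``, or the
    Otsu-derived auto range when ``spec`` is None) -> morphological
    refinement -> re-embedding at full-frame coordinates (zeros outside
    the box).
    """
    arr = _as_image(knee_slice)
    roi = crop_roi(arr, box)
    if refine.median:
        roi = ndimage.median_filter(roi, size=3)
    if spec is None:
        spec = auto_threshold(roi, otsu_fraction)
    mask_roi = threshold_segment(roi, spec)
    mask_roi = refine_mask(mask_roi, replace(refine, median=False))
    full = np.zeros(arr.shape, dtype=bool)
    r, c = box.slices
    full[r, c] = mask_roi
    return full


def load_femur_mask(path: str | Path, knee_slice: KneeSlice) -> np.ndarray:
    """Read a manual femur mask file; any positive pixel counts as mask."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # tolerate grayscale saved with channels
        arr = arr[..., 0]
    if arr.shape != knee_slice.shape:
        raise ConsistencyError(
            f"mask shape {arr.shape} does not match slice shape {knee_slice.shape}"
        )
    return arr > 0


def is_plate_visible(plate_mask: np.ndarray, min_pixels: int = 20) -> bool:
    """Visibility rule: a slice enters the sums only when the segmented
    plate has at least ``min_pixels`` positive pixels."""
    return int(np.count_nonzero(plate_mask)) >= min_pixels


def outline_overlay(
    knee_slice: KneeSlice | np.ndarray, plate_mask: np.ndarray
) -> np.ndarray:
    """Burn the mask's inner boundary into the image at maximum intensity."""
    arr = _as_image(knee_slice).copy()
    mask = np.asarray(plate_mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ConsistencyError("mask shape does not match slice shape")
    if not mask.any():
        return arr
    boundary = mask & ~erosion(mask, disk(1)).astype(bool)
    if np.issubdtype(arr.dtype, np.integer):
        peak = np.iinfo(arr.dtype).max
    else:
        peak = float(arr.max())
    arr[boundary] = peak
    return arr


#: Default physical ROI window in mm around the image centre,
#: ((y_min, y_max), (x_min, x_max)) with y running downward.  Wide enough
#: to contain the full lateral extent of the plate band plus the femur
#: region below it for every supported scanner geometry.
DEFAULT_ROI_WINDOW_MM = ((-5.0, 45.0), (-55.0, 55.0))


def default_roi_box(
    knee_slice: KneeSlice,
    window_mm: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_ROI_WINDOW_MM,
) -> BoundingBox:
    """Convert a physical mm window centred on the image into a pixel box.

    Using a physical window makes the ROI consistent across devices with
    different pixel spacing: it always frames the same anatomy.
    """
    rows, cols = knee_slice.shape
    (y_lo, y_hi), (x_lo, x_hi) = window_mm
    row_sp, col_sp = knee_slice.pixel_spacing

    def _range(n: int, sp: float, lo: float, hi: float) -> tuple[int, int]:
        centres = (np.arange(n) - (n - 1) / 2.0) * sp
        idx = np.flatnonzero((centres >= lo) & (centres <= hi))
        if idx.size == 0:
            raise ValidationError("ROI window lies outside the image")
        return int(idx[0]), int(idx[-1] + 1)

    r0, r1 = _range(rows, row_sp, y_lo, y_hi)
    c0, c1 = _range(cols, col_sp, x_lo, x_hi)
    return BoundingBox(top=r0, left=c0, height=r1 - r0, width=c1 - c0)
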