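"""Crop, range thresholding, refinement, and the full plate chain."""

import numpy as np
import imageio.v3 as iio
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from physometry import (
    BoundingBox,
    ConsistencyError,
    RefineParams,
    ThresholdSpec,
    ValidationError,
    auto_threshold,
    crop_roi,
    is_plate_visible,
    load_femur_mask,
    outline_overlay,
    refine_mask,
    segment_growth_plate,
    threshold_segment,
)
from physometry.segmentation import default_roi_box


def brute_force_threshold(image, t_min, t_max):
    """Independent per-pixel evaluation of the range-threshold rule."""
    out = np.zeros(image.shape, dtype=bool)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = t_min <= image[i, j] <= t_max
    return out


class TestThreshold:
    def test_printed_example(self):
        image = np.array([[1, 5], [9, 3]])
        mask = threshold_segment(image, ThresholdSpec(2, 6))
        assert mask.tolist() == [[False, True], [False, True]]

    def test_full_range_keeps_everything(self, rng):
        image = rng.integers(0, 255, size=(16, 16))
        mask = threshold_segment(image, ThresholdSpec(image.min(), image.max()))
        assert mask.all()

    def test_inverted_range_rejected(self):
        with pytest.raises(ValidationError):
            ThresholdSpec(5, 2)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        image=hnp.arrays(np.int64, (12, 9), elements=st.integers(0, 50)),
        lo=st.integers(0, 50),
        span=st.integers(0, 50),
    )
    def test_matches_per_pixel_oracle(self, image, lo, span):
        spec = ThresholdSpec(lo, lo + span)
        assert np.array_equal(
            threshold_segment(image, spec),
            brute_force_threshold(image, lo, lo + span),
        )


class TestCrop:
    def test_full_image_is_identity(self, rng):
        image = rng.normal(size=(10, 12))
        assert np.array_equal(crop_roi(image, BoundingBox(0, 0, 10, 12)), image)

    def test_centered_box(self, rng):
        image = rng.normal(size=(320, 320))
        patch = crop_roi(image, BoundingBox(80, 80, 160, 160))
        assert patch.shape == (160, 160)
        assert np.array_equal(patch, image[80:240, 80:240])

    def test_out_of_bounds_rejected(self, rng):
        image = rng.normal(size=(10, 10))
        with pytest.raises(ValidationError):
            crop_roi(image, BoundingBox(5, 5, 10, 10))
        with pytest.raises(ValidationError):
            BoundingBox(0, 0, 0, 5)


class TestRefine:
    def test_specks_removed_band_kept(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[18:23, 2:38] = True  # 180-px band
        mask[2, 2] = mask[2, 4] = True  # specks
        mask[35, 35] = True
        out = refine_mask(mask, RefineParams(min_component=20))
        assert out[18:23, 2:38].all()
        assert not out[2, 2] and not out[35, 35]
        assert out.sum() == 5 * 36

    def test_empty_stays_empty(self):
        assert not refine_mask(np.zeros((8, 8), dtype=bool)).any()

    def test_noise_free_plate_mask_is_fixed_point(self, clean_phantom):
        _, truth = clean_phantom
        for mask in truth.plate_masks:
            assert np.array_equal(refine_mask(mask), mask)

    def test_size_filter_idempotent(self, rng):
        mask = rng.random((30, 30)) > 0.6
        once = refine_mask(mask, RefineParams(close_radius=0, min_component=5))
        twice = refine_mask(once, RefineParams(close_radius=0, min_component=5))
        assert np.array_equal(once, twice)


class TestAutoThreshold:
    def test_bimodal_splits_modes(self, rng):
        roi = np.where(rng.random((64, 64)) < 0.2, 40.0, 200.0)
        spec = auto_threshold(roi)
        assert 40 <= spec.t_max < 200
        assert spec.t_min == 40

    def test_constant_roi_rejected(self):
        with pytest.raises(ValidationError):
            auto_threshold(np.full((8, 8), 7.0))

    def test_phantom_roi_selects_dark_band(self, noisy_phantom):
        study, truth = noisy_phantom
        knee = study.slices[3]
        mask = segment_growth_plate(knee, default_roi_box(knee))
        want = truth.plate_masks[3]
        dice = 2 * np.logical_and(mask, want).sum() / (mask.sum() + want.sum())
        assert dice >= 0.90


class TestFullChain:
    def test_noise_free_exact_recovery(self, clean_phantom):
        study, truth = clean_phantom
        for knee, want in zip(study.slices, truth.plate_masks):
            got = segment_growth_plate(knee, default_roi_box(knee))
            assert np.array_equal(got, want)

    def test_zero_outside_box(self, noisy_phantom):
        study, _ = noisy_phantom
        knee = study.slices[0]
        box = BoundingBox(40, 30, 60, 80)
        mask = segment_growth_plate(knee, box)
        outside = mask.copy()
        outside[box.slices] = False
        assert not outside.any()

    def test_range_excluding_everything_gives_empty_mask(self, clean_phantom):
        study, _ = clean_phantom
        knee = study.slices[0]
        box = default_roi_box(knee)
        mask = segment_growth_plate(knee, box, spec=ThresholdSpec(300, 400))
        assert not mask.any()


class TestFemurMaskIO:
    def test_png_round_trip(self, tmp_path, clean_phantom):
        study, truth = clean_phantom
        mask = truth.femur_masks[0]
        path = tmp_path / "m.png"
        iio.imwrite(path, mask.astype(np.uint8) * 255)
        back = load_femur_mask(path, study.slices[0])
        assert np.array_equal(back, mask)

    def test_all_zero_accepted(self, tmp_path, clean_phantom):
        study, _ = clean_phantom
        path = tmp_path / "z.png"
        iio.imwrite(path, np.zeros(study.slices[0].shape, dtype=np.uint8))
        assert not load_femur_mask(path, study.slices[0]).any()

    def test_wrong_shape_rejected(self, tmp_path, clean_phantom):
        study, _ = clean_phantom
        path = tmp_path / "w.png"
        iio.imwrite(path, np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ConsistencyError):
            load_femur_mask(path, study.slices[0])


class TestVisibilityAndOverlay:
    def test_visibility_rule(self):
        empty = np.zeros((10, 10), dtype=bool)
        assert not is_plate_visible(empty)
        mask = empty.copy()
        mask.flat[:20] = True
        assert is_plate_visible(mask, min_pixels=20)
        assert not is_plate_visible(mask, min_pixels=21)

    def test_all_slices_visible_on_default_phantoms(self, small_device):
        from physometry import PhantomSpec, generate_subject

        for age in (10.0, 18.0, 25.9):
            spec = PhantomSpec(age=age, sex="M", device=small_device, seed=2)
            study, _ = generate_subject(spec)
            for knee in study.slices:
                mask = segment_growth_plate(knee, default_roi_box(knee))
                assert is_plate_visible(mask)

    def test_overlay_empty_mask_unmodified(self, clean_phantom):
        study, _ = clean_phantom
        knee = study.slices[0]
        out = outline_overlay(knee, np.zeros(knee.shape, dtype=bool))
        assert np.array_equal(out, knee.pixels)

    def test_overlay_full_mask_is_border_ring(self, clean_phantom):
        study, _ = clean_phantom
        knee = study.slices[0]
        out = outline_overlay(knee, np.ones(knee.shape, dtype=bool))
        changed = out != knee.pixels
        interior = changed[2:-2, 2:-2]
        assert not interior.any()

    def test_overlay_boundary_within_dilated_mask(self, clean_phantom):
        from scipy import ndimage

        study, truth = clean_phantom
        knee = study.slices[0]
        mask = truth.plate_masks[0]
        out = outline_overlay(knee, mask)
        changed = out != knee.pixels
        dilated = ndimage.binary_dilation(mask, iterations=1)
        assert not (changed & ~dilated).any()
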