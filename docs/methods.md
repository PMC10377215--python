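# Methods

## Measurement model

The quantity of interest is the Area Ratio Index of the distal femoral
physis on coronal T2-weighted knee MRI.  Per slice `s` with single-pixel
area `Pix_mm² = row_spacing × col_spacing` (DICOM Pixel Spacing, tag
0028,0030):

    A_sf = Pix_mm² · N_pix(femur below plate)
    A_se = Pix_mm² · N_pix(growth plate)

Per subject, summing over the slices where the plate passes the visibility
rule (≥ `visibility_min_pixels`, default 20, of segmented plate):

    Af = Σ_s A_sf,  Ae = Σ_s A_se,  ARI = Af / Ae
    Vf = Af·Ts·Ns,  Ve = Ae·Ts·Ns,  VRI = Vf / Ve

`Ts` is Slice Thickness (tag 0018,0050) and `Ns` the visible-slice count.
Both sums run over the same slice set: a slice whose plate is not visible
contributes neither its plate nor its femur area.  `Ae = 0` (fully fused
physis) makes the index undefined and raises `FusedPlateError` rather than
returning infinity.

Two points deserve explicitness:

* **VRI ≡ ARI.**  The `Ts·Ns` factor multiplies numerator and denominator
  alike, so the volume index carries no information beyond the area index.
  A literal float evaluation of `(Af·Ts·Ns)/(Ae·Ts·Ns)` can nevertheless
  differ from `Af/Ae` in the last bit, so `measure_subject` computes VRI
  through `vri_from_areas`, which performs the cancellation algebraically;
  the literal formulas remain available as `compute_volumes`/`compute_vri`
  and agree to rounding (asserted at 1e-12 relative in tests).
* **Volume formula variant.**  A dimensional reading of a stack of `Ns`
  slabs suggests `Vf = Af·Ts` (each slice already contributes its own area
  to `Af`), whereas the definition used here multiplies the summed area by
  `Ns` as well.  Because the factor cancels from VRI, the choice has no
  effect on the ratio; both variants are exposed (`volume_mode:
  as_printed | sum_of_slabs`, default `as_printed`).

## Segmentation chain

The femur-below-plate mask is the manual step: it enters as a binary image
file (any positive pixel counts), or as a simulated observer mask in
synthetic studies.  The plate is segmented semi-automatically per slice:

1. **ROI crop.**  A fixed physical window around the physis, default
   y ∈ [−5, 45] mm, x ∈ [−55, 55] mm about the image centre, converted to
   a pixel bounding box per scanner geometry.  A physical (mm) window —
   rather than a pixel-fraction window — frames the same anatomy on every
   device regardless of field of view, which is what makes the kappa
   domain and the threshold statistics comparable across scanners.  An
   explicit pixel box can be supplied instead.
2. **Optional 3×3 median filter** on the ROI (`refine.median`, default
   off).  It is off by default because a median filter erases one- to
   two-pixel-thick bands and rounds mask corners even on noise-free
   images, destroying the exact-recovery property below; at the default
   noise level it is unnecessary (the intensity classes are ~12 SD apart).
3. **Range threshold.**  `mask = 1 iff Tmin ≤ I ≤ Tmax`, ends inclusive.
   In `auto` mode `Tmin` is the ROI minimum and `Tmax` is the lowest of
   the two three-class Otsu thresholds of the ROI histogram: a knee ROI
   holds three intensity classes (dark plate, mid soft tissue, bright
   bone), and the lowest multi-Otsu split tracks the plate/tissue boundary
   regardless of the tissue/bone mix, whereas a two-class Otsu flips
   between boundaries as class proportions change.  ROIs with fewer than
   three distinct grey levels fall back to `otsu_fraction` (default 0.6)
   times the two-class split.  Fixed `Tmin`/`Tmax` can be configured.
4. **Morphological refinement.**  Binary closing with a disk of radius
   `close_radius` (default 1; fills pinholes, never alters smooth
   boundaries), removal of 8-connected components below `min_component`
   pixels (default 20), optional keep-largest (default off).
   8-connectivity matters: the tips of a thin band connect diagonally.
5. **Re-embedding** into full-frame coordinates, zeros outside the box.

If refinement leaves a pixel in both the plate and the femur mask, the
pixel is removed from the femur mask: the ratio's semantics require the
two regions to be disjoint, and the plate boundary is the better-defined
of the two.

## Synthetic phantoms

The generator emulates exactly the features the measurement chain
consumes, in physical millimetre coordinates centred in the field of view:

* **Anatomy.**  A stylised distal femur: a 100 mm-wide shaft rectangle
  (y ∈ [−60, 48] mm) united with two condylar ellipses (centres ±28 mm,
  semi-axes 28 × 25 mm at y = 30 mm), embedded in soft tissue.  Per-slice
  lateral scaling (parabolic, up to −6% at the stack ends) mimics the
  anterior/posterior shrink of the silhouette over the ~7-slice stack.
* **Growth plate.**  A horizontal band centred at y = 15 mm of thickness
  `t(age) = max(t_min, t0 − k·age)` with defaults `t0 = 4 mm`,
  `k = 0.18 mm/yr`, `t_min = 0.8 mm`, and a wavy boundary (1.5 mm
  sinusoid, 40 mm wavelength, random per-slice phase).  The linear
  thinning model is a stand-in — no quantitative thickness-vs-age law is
  claimed — chosen to produce a strong, monotone age signal over the
  10–26 y range.  The floor `t_min` keeps the band at or above ~1.3 px
  for the coarsest supported spacing (0.625 mm): a sub-voxel band
  fragments under sampling and cannot be segmented by any
  intensity-based method, and the generated cohort is meant to contain
  only measurable plates (fused-plate handling is exercised separately
  through the error paths).
* **Intensities.**  Soft tissue 140, bone 200, plate 40 on an 8-bit-like
  scale, additive Gaussian noise (default SD 5) applied after the
  geometry is fixed; DICOM output rescales losslessly to 12 bits.
  Surrounding the bone with mid-intensity tissue (rather than air) is
  both the anatomically sensible choice and what makes the plate the
  unique dark class of any central ROI.
* **Ground truth.**  Masks are produced from the same boolean geometry as
  the rendered intensities, so with zero noise the full segmentation chain
  reproduces them pixel for pixel and the measured ARI equals the
  generator's nominal (pixel-count ratio) value exactly.
* **Cohort.**  Default 50 subjects, ages uniform on 10–26 y, sexes
  balanced, scanner drawn 11 : 30 : 9 from {3 T 320², 1.5 T 512²,
  1 T 288²} with per-subject pixel spacing uniform in the scanner's range
  (0.484–0.500 / 0.273–0.446 / 0.484–0.625 mm), slice thickness from
  {3, 4} mm and slice count from 5–9 centred on 7.  The per-subject
  geometry draws are not decoration: with fixed per-scanner geometry the
  seven technical regressors would be collinear and the device-influence
  regression unidentifiable.
* **Observers.**  Each simulated observer re-draws the manual femur mask:
  the mask's signed boundary distance is compared against a smooth random
  surface bounded by ±`perturbation` pixels (default 2), so different
  boundary stretches dilate or erode independently; zero perturbation
  reproduces the truth bit for bit.  The plate step is algorithmic and
  therefore observer-independent.

What the phantoms do **not** model: MRI physics (bias fields, coil
profiles, Rician noise), partial-volume fading at the plate boundary,
anatomical variation beyond lateral scaling, pathology, and truly fused
plates.  Passing tests therefore demonstrate that the measurement chain is
correct and device-stable on data satisfying its assumptions — not that
the biomarker performs clinically on patients.

## Statistics

* Pearson r with Fisher-z 95% CI and two-sided t test (scipy).
* Cohen's kappa from the pooled 2×2 pixel-label contingency table per
  observer pair, restricted to the segmentation ROI (background far from
  the femur would otherwise inflate agreement); CI from the large-sample
  SE `sqrt(p_o(1−p_o)/(n(1−p_e)²))`.  Scoring pixels inside the ROI,
  pooled over all slices and subjects, is this package's documented
  choice of agreement substrate.
* Mann-Whitney U: exact enumeration for tie-free samples with
  `nA·nB ≤ 400`, otherwise normal approximation with midrank tie
  correction (scipy).
* Normality: Kolmogorov-Smirnov with Lilliefors correction (statsmodels),
  since the reference normal's parameters are estimated from the sample.
* Device-influence regression: OLS of mean ARI on age, sex and seven
  technical characteristics (field strength, pixel size mm², image-matrix
  area mm², pixel count, slice thickness, visible-slice count, stack
  width Ts·Ns); per-predictor partial correlation `t/√(t²+df)`; R², F and
  model p reported.  Rank-deficient designs raise with the collinear
  columns named.  Significance level 0.05 two-sided throughout.

## Numerical and design notes

* Coordinates are 0-based, boxes half-open, (row, col) order; DICOM pixel
  spacing is kept in (row, col) order and only ever used as a product.
* Thresholds are inclusive at both ends; the threshold rule is tested
  bitwise against an exhaustive per-pixel oracle.
* Determinism: every random draw flows from `numpy.random.default_rng`
  seeded from the run seed (geometry drawn before noise, so the same seed
  yields the same anatomy at any noise level); DICOM UIDs derive from
  subject/slice indices, making rewrites byte-identical.
* Degenerate inputs fail loudly and specifically: missing Pixel Spacing /
  Slice Thickness tags name the tag; mixed within-subject geometry raises
  a consistency error; a constant ROI cannot be auto-thresholded; zero
  visible slices and zero plate area are distinct, named errors.
* Problem sizes in tests and the acceptance script: the full 50-subject
  default cohort for the parameter-recovery study (one run, shared across
  assertions), compact 160–512 px phantoms elsewhere; brute-force oracles
  run at small n where exhaustive evaluation is the point.
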