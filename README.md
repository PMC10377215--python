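# physometry

Semi-automatic growth-plate morphometry from knee MRI for skeletal-age
assessment.

## The problem

The epiphyseal growth plate (physis) of the distal femur appears on coronal
T2-weighted knee MRI as a dark horizontal band between bright bone; it thins
and finally fuses as a person matures.  Instead of assigning discrete
maturation stages, this package quantifies fusion continuously with the
**Area Ratio Index**: on every coronal slice *s* where the plate is clearly
visible, two regions are delineated — the part of the femur below the plate
and the plate band itself — and converted to physical areas using the DICOM
Pixel Spacing attribute (tag 0028,0030):

```
A_sf = Pix_mm² · N_pix(femur below plate)       A_se = Pix_mm² · N_pix(plate)

Af = Σ_s A_sf      Ae = Σ_s A_se      ARI = Af / Ae
```

A volume counterpart uses Slice Thickness Ts (tag 0018,0050) and the number
of visible slices Ns — `Vf = Af·Ts·Ns`, `Ve = Ae·Ts·Ns`, `VRI = Vf/Ve` — and
is algebraically identical to ARI because the `Ts·Ns` factor cancels.  ARI
grows with age as the plate shrinks, and because both areas are measured in
mm² from the same scanner geometry, it is in principle independent of field
strength, resolution and matrix size — the property that makes it usable
across heterogeneous MRI hardware.

The femur mask is the manual ("observer") step and is ingested as a lossless
image file; the plate is segmented semi-automatically: crop a fixed
physical region of interest around the physis, range-threshold the dark
band (`mask = 1 iff Tmin ≤ I(x,y) ≤ Tmax`, bounds derived from the ROI
histogram by a three-class Otsu split unless fixed by the user), then clean
the binary mask morphologically.

Patient imaging cannot ship with a software package, so `physometry`
includes a seeded synthetic knee-phantom generator with exact ground truth
(bone/plate/tissue intensities, age-dependent plate thickness, simulated
observers with bounded boundary jitter, DICOM serialisation).  Every claim
in the test suite is made against phantoms or against brute-force oracles.

## Worked example

```
physometry run --simulate --n 50 --seed 2023 --out report/
```

generates 50 phantoms (ages 10–26 y, scanners mixed 3 T/1.5 T/1 T at
11 : 30 : 9), segments, measures three simulated observers, and writes the
cohort report.  The same computation is available stepwise as the numbered
scripts under `analysis/`.  On this cohort they print:

```
inter-observer agreement (pooled pixel-wise kappa within ROI):
observer_pair  kappa  ci_low  ci_high  n_pixels
 Obs1 vs Obs2 0.9921  0.9920   0.9921  13331810
 Obs1 vs Obs3 0.9922  0.9921   0.9923  13331810
 Obs2 vs Obs3 0.9921  0.9920   0.9922  13331810
VRI == ARI for all 150 subject-observer rows: True

age vs mean ARI (Pearson, Fisher-z 95% CI):
 group  N      r  ci_low  ci_high   p
Female 25 0.8650  0.7138   0.9391 0.0
  Male 25 0.9538  0.8965   0.9797 0.0
 Total 50 0.8987  0.8273   0.9415 0.0

OLS on 50 subjects: R^2=0.831, F=21.82, model p=8.96e-13
age: p=6.94e-16 (significant)
device predictors: min p = 0.581 (image_matrix_area_mm2) -> none significant at 0.05
```

Reading: the three observers agree almost perfectly (κ ≈ 0.99); age
explains the ARI strongly (r = 0.90 overall, matching the generator's
noiseless value to 3 decimals), and none of the seven scanner
characteristics has a detectable effect on the measurement — the chain
recovers exactly the structure that was built into the data, which is what
a trustworthy measurement pipeline must do.

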