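# Methods

## Calibration model

A calibration phantom carries cylindrical inserts of known
hydroxyapatite concentration ρ (mg HA/cm³). The measured mean HU of each
insert is related to ρ by an affine map, and the calibration curve is
the ordinary-least-squares fit of **density on HU**,
`BMD = slope·HU + intercept`, so that applying the curve is a single
affine conversion. (The reverse parameterization — HU on density — is
equally defensible for fitting; the density-on-HU direction matches the
way the curve is consumed and makes `mean(BMD) = slope·mean(HU) +
intercept` exact by linearity.)

Insert ROIs use the detected circle shrunk by 20% (ROI radius =
0.8·detected radius) to keep partial-volume boundary voxels out of the
average. Voxel membership is a voxel-center-in-circle test in world
coordinates (mm, from the NIfTI affine), pooled over the configured
slice range. By default measurements pool the central 60% of the
phantom's z-extent — enough slices to suppress noise while avoiding the
end faces of the phantom, where axial partial-volume effects live. HU
values are pooled over the full voxel set rather than averaged per slice
and then across slices; the two are identical when per-slice counts are
equal, which holds away from the phantom ends.

### Insert detection

Inserts are located on an average of the central phantom slices. Edges
come from a Canny detector whose hysteresis thresholds are a fixed
fraction (default 1.5%, low = half of high) of the strongest smoothed
gradient in the image: the air/phantom boundary sets that scale, which
keeps the faint edge of the 0 mg HA/cm³ insert (tens of HU against the
resin) while rejecting noise, and yields thin edges so the Hough radius
is not biased outward. The circular Hough transform searches radii
within ±25% of the phantom specification; accumulator peaks above 50% of
the strongest peak become candidates.

Candidates are matched to the phantom layout by a rigid 2D point-set
fit: every (layout-pair, candidate-pair) with compatible separation
proposes a rotation+translation, the assignment problem is solved under
each, and the lowest-residual transform wins, with every insert required
to land within one insert radius of a candidate. Density labels
therefore come from geometry alone — a miscalibrated scanner cannot
scramble the density assignment, and extra circular structures in the
field of view (e.g. a bone cross-section) are ignored. Detection of
unknown phantom models is out of scope.

### Reference-scan selection

Asynchronous calibration picks a stored phantom scan by lexicographic
criteria: same scanner (mandatory), same tube voltage (mandatory — a
case with no voltage-matched reference is excluded, mirroring clinical
practice), maximal protocol agreement (kernel before protocol label),
then minimal |date difference|. Date ties go to the earlier scan so the
choice is deterministic and independent of library order.

### Table-height personalization

HU values depend piecewise-linearly (and not necessarily monotonically)
on table height, plausibly a bowtie-filter effect; the true functional
form is scanner-specific, so the generator takes it as a user-specified
knot list and the calibration side interpolates *measurements*, not
curve parameters: per-insert mean HU is interpolated linearly between
the two bracketing heights and the curve refit. This is exact at
measured heights and robust if the insert sets at different heights ever
differ. Extrapolation beyond the measured height range is refused by
default (a clamp-to-nearest override exists and warns), since the
non-monotone height dependence makes extrapolation unsafe.

## Error statistic and corrections

With in-scan calibration as ground truth, the relative error of the
asynchronous value is `d = (BMD_asyn − BMD_inscan)/BMD_inscan`, stored
as a fraction and reported in per cent. Summaries report the mean,
sample SD (n−1), maximal |d| and the R² between the two BMD series.
Covariate effects are OLS fits of d (%) on the covariate with two-sided
t-based p-values; no multiple-testing correction is applied (p-values
are per-parameter and flagged as such in reports). Paired comparisons
use Student's paired t-test; a zero-variance pairing is reported as
t = 0, p = 1 rather than an error.

The body-weight correction inverts the fitted weight–error regression
d = a·m + b (% units): `BMD_corr = BMD_asyn·(1 − (a·m + b)/100)`. The
regression is fitted on percentages while the correction consumes
fractions; the conversion happens in exactly one place
(`weight_corrected_bmd`) to avoid double-scaling. The model is
per-scanner and refuses application to a different scanner unless
forced. The kernel correction is a multiplicative factor — the mean of
per-case (reference kernel)/(other kernel) BMD ratios — because the
kernel effect observed on BMD values is well approximated as
proportional; being multiplicative, the kernel and weight corrections
commute. A correction factor ≤ 0 (weight far outside the fitted range)
is rejected as non-physical.

## Body-size covariates

The body contour is segmented by Otsu's threshold on the HU histogram,
keeping the largest connected component and filling holes slicewise.
From the mask: average slice volume (total volume / occupied slices,
cm³), polar moment of area Σ((x−x̄)²+(y−ȳ)²)dA computed per slice about
that slice's centroid and averaged over the (caller-supplied) hip slice
range (mm⁴), and BMI = weight/height² when anthropometrics are given.
Per-slice centroids make the moment translation-invariant; it scales as
s⁴ under in-plane scaling. Anatomy detection is out of scope — the hip
slice range comes from the femur mask's z-extent.

## Synthetic CT generator

The generator is the oracle for every downstream stage. A phantom scan
rasterizes a resin slab with cylindrical inserts; a subject scan
rasterizes an elliptical soft-tissue cross-section with a cylindrical
bone region, optionally with an in-scan phantom placed below the body
(+y is toward the table). Geometry uses center-of-voxel sampling with no
anti-aliasing; boundary voxels take the majority material — the 20% ROI
shrink is precisely the defense against such partial-volume voxels, so
the generator deliberately reproduces the problem rather than hiding it.
HU values are quantized to integers after all effects; noise is i.i.d.
Gaussian per voxel with no spatial correlation. All randomness flows
from a single integer seed; identical inputs give bit-identical volumes.

The noise-free value of a mineral voxel is

```
HU = intercept + slope · ρ · k · (1 + w)           (base mapping)
HU ← −1000 + (HU + 1000) · (1 + r·Δt)              (temporal drift)
HU ← HU + f(h)                                     (table-height offset)
```

with `k` the kernel factor (1 for the reference kernel, `1 +
kernel_offset` otherwise), `w` the weight bias `(a·m + b)/100` (bone
only), `r` the drift rate per year, and `f` the piecewise-linear height
offset. Drift acts multiplicatively on the HU excess over air (so air
stays at −1000 and the effect is a percent-scale change of contrast,
matching the observed percent-per-year error trend); the height offset
is additive on material voxels.

Two modelling choices matter for interpretation:

* **Weight bias.** Beam hardening is modelled as a multiplicative factor
  on the bone's mineral-equivalent signal, chosen so that the relative
  BMD error of asynchronous calibration equals `a·m + b` *by
  construction*. The observable (d linear in weight) pins down the
  error's form, not its physical mechanism; this is the simplest
  generative model with that observable.
* **In-scan phantom.** The in-scan phantom shares drift, height offset
  and — by default — the body's full beam-hardening bias, because it is
  exposed through the same body habitus. This makes in-scan calibration
  an exact ground truth, which is its defining property.
  `inscan_bias_attenuation` ∈ [0, 1] reduces the phantom's share of the
  bias for sensitivity analyses (at 1 the in-scan phantom behaves like a
  separately scanned one).

Default generative parameters (overridable per study): HU↔density slope
1 HU per mg HA/cm³ and intercept 0 (a neutral canonical mapping); drift
0.28%/yr (the long-term stability observed on a fixed-protocol scanner);
height knots (100 mm, +8 HU), (160 mm, 0), (250 mm, −10 HU) spanning the
100–250 mm range with a non-monotone kink; weight effect (−0.13 %/kg,
+8.66%); kernel offset −5% for soft-tissue kernels; noise 10 HU. The
statistical cohort layer draws weights ~ N(78, 15²) kg clipped to
35–140 kg and true BMD ~ N(413, 80²) mg HA/cm³ clipped to 150–650,
matching a mixed adult population, with a 2.6% Gaussian residual on d
for all error sources other than weight.

**What the generator does not emulate:** X-ray projection and
reconstruction physics (no sinograms, no bowtie-filter ray tracing, no
truncation artifacts at extreme table heights), spatially correlated
noise, metal artifacts, anatomical realism, or scatter. Passing tests
therefore demonstrate that the *processing chain* is correct and
self-consistent under the declared error model — not that the error
model itself describes any particular scanner. Real deployments must
fit drift, height, weight and kernel parameters per scanner.

## Numerical choices

* Volumes are integer HU (as on real scanners). A noise-free round-trip
  can only be exact to machine precision when the generative map sends
  every nominal density to an integer HU; the round-trip study uses
  slope 1.25, intercept −10 for that reason. With a generic map,
  quantization contributes up to ~0.05% relative error on an 800
  mg HA/cm³ range.
* Sample SD uses the n−1 denominator throughout.
* Regression of d on covariates is reported with slope/intercept
  standard errors so recovery can be judged in SE units.
* `hough_circle_peaks` returns integer-pixel centers and the radius grid
  is 1 px, so center and radius errors are bounded by half a voxel plus
  the matching residual; acceptance thresholds (1 voxel center, 10%
  radius) leave headroom for that discretization.

## Study problem sizes

The validation studies run at desk scale: phantom volumes of ~0.7M
voxels at 1 mm spacing (50 replicates for the noisy round-trip), 20
randomized phantoms for detection, cohorts of n = 200 × 100 replicates
for weight-effect recovery, a split-sample cohort of n = 8000 (large
enough that the held-out mean error's Monte-Carlo SD, ≈ 0.06 percentage
points, is small against the 0.2% criterion it is compared to), and a
drift study with 12 monthly phantom scans plus 10 subject scans at
1.5 × 1.5 × 3 mm. The drift study uses 1.7%/yr — a scanner whose error
roughly doubles within a year when a distant reference is used — so the
policy contrast is visible above quantization.

## Known limitations

* The replicate-root coverage reported by the weight study (fraction of
  cohort roots falling in the 62–67 kg window) is structurally limited:
  with the default effect (−0.13, 8.66) the true root, 66.6 kg, lies
  0.38 kg below the window's upper edge, while at n = 200 and 2.6%
  residual the root estimator's SD cannot fall below
  2.6/(√200·0.13) ≈ 1.41 kg whatever the weight distribution — capping
  the achievable coverage near 0.61. The study reports the measured
  fraction; interpreting it requires this context.
* Phantom detection assumes isotropic in-plane spacing and a known
  phantom model.
* DICOM support is read-only and requires rescale tags; non-uniform
  slice spacing is refused rather than resampled.
* The scanner-difference comparison is implemented as pairwise paired
  t-tests; an omnibus ANOVA variant is not provided.
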