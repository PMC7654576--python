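# Methods

## Scope and model

The package implements a bimodal retinal classification study: snapshot
hyperspectral retinal imaging (HSRI) features and OCT retinal nerve
fiber layer (RNFL) thicknesses are combined to discriminate Alzheimer's
disease (AD) patients from cognitively intact controls. Because no
patient data are distributed with the package, a synthetic phantom
generator reproduces the statistical structure the analysis assumes, so
every stage is testable against known ground truth.

## Synthetic cohort and phantom generator

**Cohort.** Subjects are drawn group-wise from the published cohort
summary of the study population this pipeline targets: AD (n = 17) and
control (n = 22) means/SDs for age, BMI, MMSE, BCVA, IOP, vertical
cup/disc ratio and the five RNFL parameters (average + four quadrants),
and group proportions for sex, eye laterality and phakic status.
Continuous draws are clipped to their legal ranges (e.g. MMSE 0–30).
A `scan_quality` index (unitless, AD 55 ± 10, control 62 ± 10) stands in
for the OCT device's signal-strength indicator used as a regression
covariate; no published value exists for it, so the defaults merely make
the covariate non-degenerate and mildly group-associated. Each AD
subject carries a latent `amyloid_load ~ LogNormal(0, 0.25)` (strictly
positive, right-skewed severity); controls have load 0.

**Spectral effect.** AD reflectance is attenuated per band by
`1 − a · load · (460/λ)⁴`, a Rayleigh-scattering law for small soluble
aggregates: maximal below 550 nm, fading with wavelength. The magnitude
`a` (`scatter_amplitude`, default 0.1) is a free simulation parameter —
no reflectance-unit effect size is published — and 0 disables the group
difference entirely.

**Phantom.** Each subject's retina is a 272 × 512 × 16 relative-
reflectance cube: a smooth wavelength-increasing fundus spectrum, a
low-frequency multiplicative gain field, a bright optic disc and a
foveal dip, a vessel tree (about 8–11% of pixels) with a hemoglobin-like
Gaussian absorption dip centred at 560 nm (depth 0.4), and i.i.d. pixel
noise (SD 0.02 reflectance units). Phantoms are generated in right-eye
convention and mirrored for left eyes so that laterality handling in the
ROI geometry is genuinely exercised. The OD–fovea distance is drawn
uniformly from 18.6–20.0% of the image width (95–102 px at full scale)
with small jitter and axis tilt; this is the upper part of the clinical
range that still leaves the default ROI layout (far offset 0.85·D plus
40 px of ROI height) inside the 272-row frame.

**Sensor.** The camera model maps the cube through the 4×4
filter-mosaic: band *b* sits at `(b // 4, b mod 4)` in each block (the
true filter layout is proprietary; any fixed bijection is equivalent
because demosaicing inverts it), band centers are 465 + 10·b nm, and
`raw = dark + R·(white − dark) + read noise`, clipped at the 16-bit
saturation level. Dark level 64 DN, white reference rising 38 000 →
51 500 DN across bands, read noise 20 DN.

## Preprocessing

* **Demosaic** is pure reorganisation (no interpolation) and has an
  exact inverse, which the tests verify as a round trip.
* **Reflectance** `R = (DN − dark)/(white − dark)` is clipped below at
  0: read noise makes small negatives inevitable and downstream
  standardization requires non-negative values.
* **Saturation QC** implements the capture rule "maximum intensity
  without saturating outside the optic nerve head": a frame is usable
  when at most 0.1% of pixels outside the ONH disc reach saturation.
* **Vessel masking** works on the mean of the 540–580 nm bands, where
  hemoglobin absorption makes vessels dark. The image is divided by a
  Gaussian illumination estimate (σ = 25 px) — making the detector
  exactly invariant to global intensity scaling — then filtered with a
  multiscale Sato ridge filter (σ = 1–3 px), thresholded at the 90th
  percentile of the response (with a small absolute floor so
  structure-free images give empty masks), and cleaned of components
  under 50 px. On default phantoms this achieves pixel recall ≥ 0.8 and
  precision ≥ 0.7 against the generator's truth, and ROI spectra
  computed after masking stay within 1% of vessel-free truth.

## ROI geometry and features

The image frame is rotated so the OD→fovea direction is the +u axis
(left eyes mirrored first). All four ROIs are `round(0.35·D)` wide,
40 px tall, horizontally centred over the midpoint of the OD–fovea
segment; the near edges of S1/I1 sit 0.35·D from the axis and those of
S2/I2 at 0.85·D. The 0.5·D gap between near and far ROIs exceeds the
40 px height whenever D > 80 px, so the rectangles cannot overlap. The
vertical offsets are design choices (the published description fixes
only height, width and non-overlap) and are exposed as configuration.
Pixels are rastered with floor rounding and half-open bounds;
equivariance to translation and mirroring is tested exactly.

Standardization drops the two edge bands — the noisiest filters on a
mosaic sensor — and divides the remaining 14 values by their own mean,
making features scale-free. The published procedure fixes only the
output length (14); the mechanism here is the package's choice. The
`+RNFL` configurations append (AVG, SUP, NAS, INF, TEM) in μm.

## Statistics

Pooled-variance (not Welch) two-sample t tests reproduce the printed
age p-value (0.191 from rounded summaries vs 0.193 printed); Pearson
chi-square without continuity correction reproduces the printed
laterality (0.408) and phakia (0.024) p-values — the corrected variants
do not. The Mann-Whitney test uses exact enumeration when `n1·n2 ≤ 400`
and the data are tie-free, otherwise the tie-corrected normal
approximation. RNFL group effects are OLS-adjusted for age, gender and
scan quality (df = n − 5) and Bonferroni-corrected with m = 5.

The SEM screen selects an ROI when the groups' mean spectra ± 1 SEM are
disjoint at ≥ 1 band. The ±1 SEM rule has a high per-band false-positive
rate (~16%), so its behaviour depends strongly on the between-band
correlation of subject spectra: with realistic, strongly correlated
spectral noise a null ROI passes rarely, with independent band noise it
passes almost always. The screen's simulation test therefore uses
band-correlated noise with the effect confined to two ROIs. By default
the screen runs once on the full cohort (replicating the original
analysis); `strict_screening` re-runs it inside each outer training
fold to avoid selection leakage, recording the per-fold candidate sets.

## Classifier and evaluation

LDA uses class means, pooled within-class covariance (divisor n − 2) and
empirical priors; posteriors are the two-class softmax of the linear
discriminants. A ridge `ε = 1e-8 · trace(Σ)/p` is added to Σ — the one
departure from the textbook estimator — sized to keep exactly collinear
feature sets solvable while staying below the 1e-6 posterior agreement
that the test suite demands against a reference implementation.
Features are z-scored per feature on the training fold only (default
on), so μm-scale RNFL features cannot dominate the covariance.

Nested LOOCV: each outer fold holds out one subject, scores every
candidate configuration by inner LOOCV AUC on the remaining n − 1
(ties broken toward fewer features, then a fixed configuration order),
refits the winner and records the held-out AD probability. The outer
AUC over pooled held-out probabilities gets a DeLong structural-
components Wald interval (a stratified percentile bootstrap is available
via `ci_method="bootstrap"`). Inner folds that lose a class are skipped
with a warning rather than aborting the run.

On label-permuted data the nested outer AUC averages ≈ 0.47–0.48 over
100 replicates — near chance, with the small remaining deficit being the
well-known pessimistic bias of pooled leave-one-out scores (holding a
subject out shifts its class mean and the empirical priors away from
it). Single-level LOOCV with post-hoc selection of the best of four
configurations averages ≈ 0.57–0.60 on the same null data, which is the
optimism that nesting exists to remove.

## Problem sizes and numerical choices

Tests run reduced problem sizes chosen to preserve every code path:
phantoms at 224 × 384 for pipeline tests (full 272 × 512 for the
vessel-segmentation scoring), cohorts of 4–10 subjects for structural
checks, 100 replicates for the null-calibration simulation, 200 score
sets × 2000 bootstrap replicates for the CI-width comparison. The
acceptance script runs the full-scale 17 + 22 study. Degenerate inputs
are handled explicitly: zero-variance features in z-scoring fall back to
SD 1; chi-square tables with empty margins are reported as degenerate in
the cohort table rather than aborting tiny simulated cohorts; reflectance
negatives are clipped; saturation inside the ONH disc is tolerated.

## Known limitations

* Phantoms have almost no between-subject spectral variability after
  standardization (the gain field cancels in the per-spectrum mean
  normalization), so at the default `scatter_amplitude = 0.1` the
  synthetic classification task is far easier than the clinical one —
  the default study separates perfectly. Passing tests demonstrate the
  pipeline's correctness and the evaluation machinery's calibration, not
  clinical effect sizes; set `scatter_amplitude = 0` for null behaviour.
* The amyloid effect is spatially uniform across the retina, so all four
  ROIs typically pass the SEM screen on synthetic data; regional
  selection patterns seen clinically arise from spatial heterogeneity
  the phantom does not model.
* No point-spread function, media opacity, vignetting correction,
  registration across captures, or spectral filter crosstalk correction
  (the last is left as a configuration extension point).
* Optic-disc and fovea locations are taken as given (clinically they are
  marked manually); automatic landmark detection is out of scope.
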