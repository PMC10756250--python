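# Methods

## Phantom model

Each synthetic subject carries two eyes on an orbit-cropped grid
(96×96×64 mm at 1 mm isotropic voxels; axis order LR, PA, IS in RAS world
coordinates).  An eye is a three-compartment geometric model:

* **globe** — an ellipsoid with semi-axes along the eye's anatomic AP, SI
  and LR directions; its full AP extent is the MRI axial length;
* **lens** — an oblate ellipsoid on the AP axis whose anterior surface
  touches the anterior-chamber plane; its radius is derived from a target
  lens volume given the sampled thickness;
* **anterior chamber (AC)** — the spherical-cap slab of the globe anterior
  to that plane; the **posterior segment (PS)** is the remaining globe.

This is deliberately not a biophysical eye: the analysis only measures
these three compartments, so a model with exactly those degrees of freedom
is sufficient to exercise segmentation, geometry and statistics.  Cornea
and sclera are not modelled (they are effectively invisible on
fat-suppressed T2 at this resolution), and no k-space/acquisition physics,
braces artifacts or pathology are simulated.

### Generative calibration

True geometry is drawn from group-conditional normals for the three
refraction groups (myopia / emmetropia / hyperopia, default proportions
12.3 % / 80.2 % / 7.5 %).  Group means and SDs for PS length, height and
width follow the reference cohort values for 10-year-old children
(e.g. PS length 16.2 / 16.9 / 17.7 mm for hyperopic / emmetropic / myopic
eyes).  Two parameters are not reported per group and were calibrated once
from derived quantities:

* **ACD (2.30 / 2.75 / 3.15 mm) and lens thickness (3.2 mm)** — chosen so
  the implied group-mean sphericities (height²/AL²−1 ≈ 0.11 / 0.06 / 0.01)
  and the emmetropic axial length (≈ 22.9 mm) match the reported pattern;
  a deeper anterior chamber in myopes is also physiologically expected.
* **shared latent size factor (loading 0.7 of each dimension's SD)** —
  a single per-subject factor loading on all eye dimensions and, with
  smaller loadings, on body height (0.45), birth weight (0.30) and
  gestational age (0.08).  0.7 reproduces inter-dimension correlations of
  ~0.5–0.65 (height–width, AL–height), matching what school-age cohorts
  report; without it, within-group shape variance would be far too large
  and shape–refraction correlations would vanish.

A per-eye jitter (0.2 of the dimension SD) keeps the two eyes of a subject
highly but not perfectly correlated; the within-group variance budget
(loading² + jitter² + residual²) always sums to the configured SD².
Spherical equivalent is drawn from group-conditional truncated normals
consistent with the group cut-offs (myopia ≤ −0.5 D, hyperopia ≥ +2.0 D);
axial-length growth rate (0.21 ± 0.09 mm/y) is correlated with SE at −0.4.
Physically impossible draws are rejected and redrawn (error after 100
rejections).

Intensities mimic fat-suppressed T2 contrast: vitreous 1000, aqueous 950,
lens 250, orbital soft tissue 350, air 50 (arbitrary units), plus additive
Gaussian noise (SD 20 by default — SNR ≈ 50 in vitreous) and optional
Gaussian motion blur (off by default, matching a quality-controlled
cohort).  Noise is seeded from the subject id, so rendering is a pure
function of the spec.  A Rician noise model was considered and left out:
at this SNR the Gaussian approximation is indistinguishable for the
segmentation task.

### Optical-biometry emulation

The optical instrument measures cornea-to-retinal-pigment-epithelium,
while the MRI segmentation spans the vitreoretinal surface; emulated
axial length therefore reads `delta_al` (default +0.18 mm) longer than the
true AP extent, with Gaussian difference noise of SD 0.454 mm — the SD
implied by 95 % limits of agreement spanning (−0.71, +1.07) mm around the
offset.  Emulated ACD adds a +0.9 mm corneal offset.  Pupil diameter is
sampled so a configurable fraction (default 10 %) fails the ≥ 6.0 mm
cycloplegia criterion.

### What the phantoms do not capture

Real orbital MRI has partial-volume mixtures, intensity inhomogeneity,
motion, off-axis gaze, and anatomies that are not ellipsoids.  Passing the
cross-validation floors on phantoms therefore shows the *pipeline* is
implemented correctly and is an upper bound on clean data — not that the
method reaches those Dice values on clinical scans.  Likewise the
cohort-level correlations are recovered from a generator calibrated to the
reported values, so they validate sign and rough magnitude propagation
through the pipeline, not the epidemiology itself.

## Segmentation

* **Registration** — single-stage transform (affine by default; rigid /
  translation / identity selectable) with a mean-squared-error metric,
  regular sampling of 25 % of voxels, multi-resolution shrink factors
  (4, 2) with smoothing sigmas (2, 1) mm, regular-step gradient descent
  (≤100 iterations), scales from physical shift.  The transform starts at
  identity with its center at the fixed-image center: atlases and targets
  share the acquisition FOV, so re-centering initializers are unnecessary
  and would mask genuinely disjoint inputs.  A registration is flagged
  diverged — and excluded from fusion — if the optimizer throws, the final
  metric is worse than the starting metric, or under 5 % of the target FOV
  maps inside the atlas.  Deformable registration is not needed for
  ellipsoidal anatomy and is out of scope.
* **Label warping** — one-hot labels resampled with linear interpolation
  (soft maps; nearest-neighbour selectable); residual mass (including
  regions mapping outside the atlas) is assigned to background so each
  voxel's vector sums to 1.
* **Fusion** — voxel-wise class frequency across converged atlases,
  normalized.  By default 5 atlases are registered per target (drawn from
  the training split): fusing more improves the prior marginally on
  phantoms while multiplying runtime.
* **Features** — 48 per voxel: for each scale σ ∈ {1.0, 1.6, 4.0} mm the
  Gaussian-smoothed intensity, 3 first derivatives, 6 second derivatives,
  gradient magnitude, Laplacian, 3 Hessian eigenvalues (ascending) and the
  Hessian determinant.  The derivative families alone give 15 per scale;
  including the smoothed intensity itself (the natural zeroth-order
  member of the scale-space family) reaches the 16 × 3 = 48 layout.
  Derivatives are computed in mm via spacing-corrected Gaussian-derivative
  filters, so the features are resolution-independent.
* **Classifier** — random forest, 100 trees, unlimited depth, √48 features
  per split, class-balanced subsampling of at most 2 500 voxels per class
  per training subject (caps the fit cost; small classes such as the lens
  contribute every voxel), seeded.  The background bias is a multiplicative
  down-weight β = 0.5 on the background probability with per-voxel
  renormalization (β = 1 is a no-op); its exact form and size are free
  parameters of the method and exposed in config.
* **Combination** — argmax of (atlas prior + ε)·(classifier map) with
  ε = 0.01: the additive floor prevents a unanimous-zero atlas prior from
  annihilating the classifier.  Ties break deterministically toward the
  lower class code (background first).  Voxels outside a dilated
  (4 mm) envelope of the fused prior are classified as background without
  running the forest — the prior is unanimous background there, so the
  product's argmax cannot be anything else; this is purely a compute
  saving.
* **Left and right eyes are distinct classes** (six regions + background),
  not a mirrored single eye.

Cross-validation renders the cohort once, extracts each subject's training
subsample once (reused across folds), trains one forest per fold on the
training split only, and reports per-class Dice mean ± SD over all test
subjects of all folds.  Everything is driven by one seed; two runs with the
same seed produce identical fold assignments, forests and Dice tables.

## Geometry

* **Axes** — AP = unit vector from PS centroid to lens centroid;
  SI = unit(AP × u), u the unit vector from right-PS to left-PS centroid,
  sign fixed so SI points superiorly (+z in RAS); LR = AP × SI.  Centroids
  are unweighted means of voxel centers.  Degenerate anatomy (missing
  compartment, collinear AP and inter-eye direction) raises with the side
  and class named.
* **Chords** — lengths are measured as the distance between the first and
  last 0.5-level crossings of the trilinearly interpolated compartment mask
  along a line, sampled at 0.25 × the smallest voxel spacing, with linear
  interpolation of the crossing position.  This sub-voxel convention
  reduces the 1 mm quantization on 17–24 mm structures; on binary
  voxelizations each surface crossing is still only determined to ±0.5
  voxel, which bounds length accuracy at ±1 voxel.  The measurement line
  for all AP-axis quantities passes through the PS centroid (the natural
  anchor; lens and AC are on that axis by construction).  A line that
  reaches the FOV boundary while still inside the mask is an error (the
  structure is cut), as is an anchor outside the mask.
* **Axial length** is the extent of PS ∪ lens ∪ AC along the AP line and
  decomposes into PS length + lens thickness + ACD; the lens term is
  reported separately so the decomposition is explicit.
* **Sphericity** — hS pairs *height* with axial length and vS pairs
  *width* with axial length, exactly as conventionally printed.  The
  naming is anatomically debatable (height is a vertical dimension yet
  defines "horizontal" sphericity), so `swap_sphericity_labels` exchanges
  the two without touching the numbers; the default follows the printed
  convention.  Threshold ±0.005 with boundary values classed spherical.
* **Volumes** are voxel counts × voxel volume — no surface fitting.

## Statistics

* SE = sphere + cylinder/2; boundary −0.5 D belongs to myopia and +2.0 D
  to hyperopia (the emmetropic interval is open on both ends).
* Exclusions: scan-quality failures leave all analyses; inadequate
  cycloplegia (pupil < 6.0 mm, strict) leaves SE-based analyses only;
  complete-case handling per table.  No multiple-testing correction is
  applied.
* Pearson correlation with two-sided t-based p; one-way ANOVA for
  continuous group comparisons; Pearson chi-square (no continuity
  correction) for shape-class proportions.
* Restricted cubic splines use the Harrell truncated-power basis (linear
  term + k−2 curvature terms scaled by the squared knot span), knots at
  the 10th/50th/90th percentiles for k = 3, fitted by OLS; the basis spans
  linear functions exactly and is linear beyond the boundary knots by
  construction.  Fitting y = x² on [0,1] with 3 knots leaves a maximum
  absolute error of ≈0.022 (at the boundary-linear tails; ≈0.010 within
  the knot span) — the irreducible approximation error of this basis.
* Bland–Altman: difference mean and mean ± 1.96·SD (sample SD) as limits
  of agreement.
* Group analyses use the right eye by default (averaging both eyes is a
  config option); per-subject sphericities are averaged as values, not
  recomputed from averaged dimensions.

## Problem sizes and numerical choices

The shipped analyses use a 30-subject, 3-fold cross-validation at 1 mm
voxels (the number of manually segmented atlas scans a study of this kind
realistically has) and 2 963-subject tabular cohorts for the statistical
stages, which render nothing and run in seconds.  Dice on these clean
phantoms runs ~0.99 (PS and lens) and ~0.93 (AC, whose thin cap suffers
most from partial-volume at 1 mm).  All randomness flows from
`numpy.random.Generator` objects seeded at the entry points; registration
sampling, forest training, fold assignment and noise synthesis derive
their seeds from those, so every pipeline product is reproducible
bit-for-bit given the seed.

## Known limitations

* The phantom AC volume tracks its cap geometry, not an independently
  calibrated mean; with the shape-calibrated ACDs the hyperopic group's AC
  volume runs ~20 % below its reported mean.  Shape calibration was
  preferred because the shape–refraction structure is what the statistics
  stage consumes.
* No deformable registration stage; adequate for ellipsoidal phantoms,
  selectable architecture but unimplemented.
* Visual quality control is represented only by a pass/fail flag in the
  cohort table.
* Joint covariances between covariates (body height, birth weight) and
  eye dimensions are emulated through a single latent factor; the true
  joint covariance of a real cohort is richer, and reported
  variance-explained figures are not a calibration target.
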