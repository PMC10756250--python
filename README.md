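# oculomri

Eye size and shape from orbital MRI, end to end: synthetic orbital-phantom
generation, automated six-region eye segmentation, 3D anatomic-axis
biometry, and the cohort statistics that relate eye shape to refractive
error in school-age children.

## The problem

Optical biometry measures a single axial length along the visual axis.
T2-weighted MRI of the orbits sees the whole globe, so it can also measure
the eye's height, width, compartment volumes and three-dimensional *shape* —
whether the globe is flattened (oblate) or elongated (prolate) along its
optical axis — independently of the eye's optics.  In population cohorts
these shape parameters are studied against cycloplegic refractive error:
myopic eyes are longer, larger and more prolate.  The cohort data such
studies use are not public, so this package ships a calibrated synthetic
phantom cohort on which every stage of the analysis runs and is tested.

## The method

**Segmentation.**  Each scan is segmented into six regions (posterior
segment, lens and anterior chamber, for each eye) by multiplying two
per-voxel class-probability maps and taking the argmax:

1. *atlas fusion* — labelled atlas scans are affinely registered to the
   target and their warped labels averaged into a spatial prior;
2. *voxel classification* — a random forest on 48 scale-space features per
   voxel (Gaussian-smoothed intensity, 3 first and 6 second derivatives,
   gradient magnitude, Laplacian, 3 Hessian eigenvalues and the Hessian
   determinant, at scales σ ∈ {1.0, 1.6, 4.0} mm), with the background
   probability down-weighted by a bias β so eye tissue that locally looks
   like background is not over-ruled.

Quality is evaluated with per-class Dice under seeded k-fold
cross-validation.

**Biometry.**  Per eye, the anterior-posterior (AP) axis runs from the
posterior-segment centroid to the lens centroid; the superior-inferior (SI)
axis is normal to the plane spanned by AP and the inter-eye direction; the
left-right (LR) axis completes the right-handed frame.  Height and width
are sub-voxel chords of the posterior-segment mask along SI and LR through
its centroid; the axial length along AP decomposes into posterior-segment
length, lens thickness and anterior-chamber depth.  Volumes are voxel
counts × voxel volume.  Sphericity compares a transverse diameter d with
the axial length AL:

    S = d² / AL² − 1,   S > 0.005 oblate,  S < −0.005 prolate,  else spherical.

**Statistics.**  Spherical equivalent SE = sphere + cylinder/2; groups are
myopia (SE ≤ −0.5 D), hyperopia (SE ≥ +2.0 D), emmetropia in between.
Pearson correlations, one-way ANOVA / Pearson chi-square across groups,
restricted-cubic-spline regression (3 knots at the 10th/50th/90th
percentiles), and Bland–Altman limits of agreement for
optical-biometry-vs-MRI axial length.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/04_cohort_statistics.py
python analysis/05_method_agreement.py
```

prints (seed 1, n = 2963):

```
simulated 2963 subjects (seed 1)
  myopia       13.1 %
  emmetropia   79.4 %
  hyperopia     7.5 %
  mean PS length   16.95 mm (SD 0.79)
...
myopia - hyperopia  PS length: +1.48 mm
corr(SE, ps_length) r = -0.386  (p = 3e-95)
corr(SE, hs       ) r = +0.253  (p = 3.6e-40)
oblate overall: 75.1 %; prolate among myopes: 40.6 %
...
mean difference (biometry - MRI): +0.187 mm
95% limits of agreement: (-0.683, +1.058) mm
```

Myopic phantom eyes have longer posterior segments (+1.48 mm vs hyperopic
eyes), sphericity increases with hyperopia (positive SE–shape correlation),
most eyes are oblate while prolate shapes concentrate among myopes, and the
built-in +0.18 mm instrument offset between optical and MRI axial length is
recovered by the Bland–Altman analysis.  `analysis/02_crossval_segmentation.py`
cross-validates the segmentation itself (~15 min), and
`analysis/03_measure_biometry.py` audits the geometry measurements against
the generative truth (lengths recover within one 1-mm voxel).

There is also a CLI (`oculomri generate|segment|crossval|measure|report|run`)
wrapping the same library calls.

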