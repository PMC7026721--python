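# Methods

## Problem and model

The package quantifies tumor-associated angiogenesis in 3D microvascular
images. Its working assumptions: (i) a vessel is an unbranched centerline,
an ordered 3D polyline in mm; (ii) tortuosity is measured *after* resampling
the centerline to uniform 50 μm arc-length spacing, because the sum-of-angles
metric (SOAM) is a discrete total-curvature density and depends on sampling;
(iii) tumor neovasculature is both more tortuous and spatially concentrated,
so a density-based cluster of high-SOAM vessels is the tumor signature.

Metric definitions and conventions:

* DM = path length / endpoint chord. Undefined for closed loops (coincident
  endpoints); such vessels raise a flagged error and are excluded from image
  means, counted in the QC output. Two-point centerlines give DM = 1.
* SOAM = Σ turning angles / path length, with dot products clamped to
  [−1, 1] before arccos to avoid NaN from floating-point overshoot.
  Centerlines with fewer than 3 points return 0 and are treated as
  degenerate. Both metrics are invariant under rigid motion; DM under
  uniform scaling; SOAM scales as 1/scale.

## Clustering detector

Candidate vessels are those with SOAM above an absolute threshold,
default 3.5 rad/mm — between the typical control (≈3.1) and tumor (≈3.6)
image-level means; a cohort-percentile rule is available as an alternative.
Each candidate contributes one DBSCAN point, its centerline centroid, in
units of the 50 μm resampling grid so that the neighborhood radius ε = 27
corresponds to 1.35 mm; this unit conversion lives in exactly one place
(`clustering.vessel_features`). min_pts = 4 counts the point itself. DBSCAN
is implemented in-package to pin down otherwise unspecified behavior: core
points are connected through ε-adjacency (union-find), clusters are numbered
by their lowest member index, and a border point joins its *nearest* core
point with ties broken toward the lowest index — fully deterministic, which
a scan-order-dependent border assignment is not. Noise never contributes to
cluster sizes. An image is called tumor when the maximum cluster size is at
least the cutoff (default 8, inclusive).

## Reader model and ROC regression

Ordinal reader scores are modeled as a discretized latent-probit process:
latent = reader bias + (class separation + β·diameter)·1{tumor} + shared
image effect + reader noise, cut at five fixed thresholds into scores 1–6.
The shared image effect (SD 0.8) represents per-image vascular visibility;
it is what makes readers concordant (Kendall's W ≈ 0.73 at defaults) without
inflating pooled-reader discrimination, and with reader noise SD 0.6 the
marginal latent noise is 1.

The covariate-adjusted ROC regression ROC_x(p) = Φ(α₀ₖ + α₁Φ⁻¹(p) + βx) is
estimated by the placement-value approach: each tumor score is mapped to its
placement in that reader's empirical control survival distribution (midrank
tie handling, clamped to the open unit interval at half a control mass unit
so probit transforms stay finite when supports do not overlap), and the
indicators 1{PV ≤ p} are regressed with a binomial GLM (probit link) on
reader dummies, Φ⁻¹(p) and the diameter. The FPR grid is the set of distinct
control placement values pooled over readers, capped at 50 points by
quantile thinning. Standard errors and percentile CIs come from a bootstrap
that resamples whole images stratified by class, preserving within-image
correlation across readers; percentile (not normal-approximation) intervals
are used because n is small and the metrics skewed. On continuous binormal
panels with unit noise the true coefficients are α₁ = 1 and β equal to the
latent diameter effect; simulation shows the estimator recovers β with bias
under 5% at the default study size (7 readers, 31 tumors, 17 controls).

Everywhere, the positive decision rule is score ≥ threshold. Youden
operating points break ties toward higher specificity; fixed-sensitivity or
fixed-specificity operating points search finite observed thresholds only,
so an unattainable constraint errors rather than silently returning the
degenerate all-negative point.

The Wilcoxon rank-sum comparison uses midranks; with both groups ≤ 10 the
two-sided p-value is exact, computed from the subset-sum distribution of the
doubled midranks, otherwise a tie- and continuity-corrected normal
approximation is used (the branches agree within 0.02 at the crossover).

## Synthetic cohort generator

The generator emulates the study conditions, not ultrasound physics: no
speckle, attenuation, or microbubble kinetics — rasterization is a
tube-plus-Gaussian-blur model only. Defaults (all configurable in
`SynthParams`):

* **Cohort**: 31 tumor / 17 control images, 40–60 background vessels each in
  a 25×25×25 mm field of view.
* **Tumor diameters**: lognormal, median 2.3 mm, truncated to [0.8, 8.2] mm
  (skewed toward small tumors).
* **Vessel waviness**: a centerline grows in 50 μm steps; the heading turns
  by |N(0, σ)| about a perpendicular axis whose azimuth drifts as an AR(1)
  process. Since the per-step turning angle equals the applied rotation,
  E[SOAM] = target exactly when σ = target·step·√(π/2) — the calibration is
  closed-form, and Monte-Carlo tests confirm the realized group means land
  within a few percent (resampling smooths ~2–3% off). The axis-drift rate
  decouples SOAM from DM: fast drift (background, 1.5 rad/step) yields
  jittery but globally straight vessels (low DM), slow drift (tumor
  neovessels, 0.2) yields coils (high DM) — reproducing the observation that
  SOAM separates the groups strongly while DM separates them weakly.
* **Tortuosity targets** are image-level mean SOAM: control 3.09, tumor
  3.61 rad/mm. The per-vessel background target is solved from the mixture
  so the image-level mean hits its target; tumor neovessels use a fixed
  per-vessel target (4.4 rad/mm) chosen so the tumor image mean lands at its
  target given mean cluster sizes.
* **Tumor cluster**: vessel count = 20·d^0.7 · lognormal(σ=0.55) noise
  (floor 6), calibrated so the realized maximum cluster size is ≈34 ± 30
  vessels with a weak positive size relation (R² ≈ 0.4); sublinear because
  cluster size grows with, but is not proportional to, diameter. Cluster
  vessels start within 0.15·d of the tumor center with arc length 0.3·d, so
  every centerline point is within d/2 of the center by the triangle
  inequality — containment by construction, never by post-hoc rescaling
  (which would distort SOAM).
* **Controls** additionally contain one compact benign vascular confluence
  ("knot") of round(N(5.4, 1.4)) mildly tortuous vessels — the counterpart
  of the small clusters healthy images produce — so the control maximum
  cluster size is ≈5 ± 2 rather than 0 and specificity at the 8-vessel
  cutoff is ≈0.94. Tumor images share the same background anatomy.

A cohort seed spawns per-image child seeds (`numpy.random.SeedSequence`), so
cohorts are reproducible and any image independently regenerable.

What passing tests on this generator do **not** show: performance on real
acoustic-angiography data (point-spread anisotropy, vessel branching,
segmentation failure modes, reader behavior). The printed in vivo results
are not reproducible from synthetic data and are not asserted anywhere; the
tests check method properties (orderings, recoveries, calibrations), not
those numbers.

## Imaging stage

Rasterization marks voxels within a radius of the densely-sampled polyline,
then applies isotropic Gaussian blur and optional additive noise (clipped at
0). Isotropic interpolation resamples each axis linearly; grid positions
that coincide with original planes are copied bit-identically. Seeds are
local maxima above a fraction of the global max, greedily thinned to a
minimum Euclidean separation in intensity order. Ridge traversal requires an
isotropic volume: the volume is pre-smoothed at 2–3 Gaussian scales
(0.1–0.2 mm) and the scale with the largest response at the seed is used for
the whole traversal; at each 1-voxel step the walker moves along the Hessian
eigenvector of smallest-magnitude eigenvalue (sign-aligned with the previous
heading), re-centers on the intensity centroid of the orthogonal disk, and
stops at the intensity threshold, a turn sharper than 75°, the grid edge, or
a step cap. Forward and backward half-paths are concatenated; the vessel
radius is estimated from the half-maximum of the orthogonal intensity
profile. Extraction de-duplicates traversals whose points overlap a prior
vessel by more than 50% within 0.25 mm and lightly smooths recovered
polylines (5-point moving average) before resampling, suppressing voxel
jitter that would inflate SOAM. The traversal is an automated simplification
of multiscale ridge tracking; its acceptance standard is geometric recovery
on synthetic tubes (sub-half-voxel axis error, <5% arc-length error,
Spearman ρ > 0.8 between true and recovered SOAM), not equivalence with any
interactive tool.

Conventions: axis order (axial, lateral, elevation); 0-based voxel centers;
position = origin + index·spacing; lengths in mm in all files.

## Problem sizes and numerical choices

Simulation-based tests use the study-sized cohort (48 images) and the
replicate counts their checks require (200 recovery replicates, 100 null
replicates, 500 coverage simulations); bootstrap replicates inside those
loops are 100–500, sufficient for SE estimation, while the headline analysis
default stays at 1000. The segmentation demo and tests use a reduced 0.1 mm
grid. Ties: Youden → higher specificity; DBSCAN border points → lowest
vessel id; rank ties → midranks throughout.

## Known limitations

* Vessels are independent open polylines; no branching topology, and the
  clustering feature is the centroid only (appending scaled DM/SOAM to the
  feature vector is available but off by default).
* The ε = 27 neighborhood is interpreted in resampling-grid units; other
  unit interpretations are representable through `ClusterConfig`.
* The ROC-regression estimator is a placement-value GLM; other estimators of
  the same model may differ in finite samples. Its validation here is
  simulation recovery, not coefficient-level equality with any specific
  implementation.
* The generator matches printed group summaries, not per-image distribution
  shapes, which no available data constrain.
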