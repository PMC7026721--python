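# angioquant

Tumor detection from 3D microvascular images via vessel tortuosity and
spatial clustering.

Contrast-enhanced superharmonic ultrasound ("acoustic angiography") resolves
microvessels of ~100–200 μm in vivo. Tumor-associated angiogenesis produces
vessels that are abnormally tortuous and spatially concentrated, which makes
vascular geometry a usable imaging biomarker: an image can be classified as
tumor-bearing or healthy from the geometry of its vessels alone. This
package implements that quantitative analysis end to end for researchers in
vascular image analysis, together with a synthetic cohort generator that
replaces the (undeposited) in vivo mouse data, so every stage is testable
and reproducible from a single seed.

## The method

For each vessel centerline p₁…pₙ (ordered 3D points, mm, resampled to 50 μm
arc-length spacing) two tortuosity metrics are computed:

* **Distance metric (DM)** — path length over endpoint chord:
  `DM = Σₓ |pₓ − pₓ₊₁| / |p₁ − pₙ|`, dimensionless, ≥ 1;
* **Sum-of-angles metric (SOAM)** — total turning angle per unit path
  length: `SOAM = Σₓ arccos(ν̂ₓ·ν̂ₓ₊₁) / Σₓ |pₓ − pₓ₊₁|` with
  νₓ = pₓ₊₁ − pₓ, in rad/mm.

Images are classified three ways:

1. **mean DM** and 2. **mean SOAM** over all vessels, thresholded;
3. **maximum cluster size**: vessels with SOAM > 3.5 rad/mm are clustered by
   DBSCAN on their centerline centroids (min_pts = 4, ε = 27 grid units =
   1.35 mm) and an image is called tumor when its largest cluster holds at
   least 8 vessels.

A simulated 7-reader panel scores each image on an ordinal 1–6 malignancy
scale; reader performance is summarized by Kendall's W, the pooled ROC, and
a covariate-adjusted ROC regression with probit link,

    ROC_x(p) = Φ( α₀ₖ + α₁·Φ⁻¹(p) + β·x ),

fitted by placement values against each reader's empirical control survival
function, with bootstrap standard errors resampling whole images. β measures
how discrimination improves per mm of tumor diameter x.

Segmentation utilities (isotropic interpolation, seed detection, multiscale
Hessian ridge traversal) recover centerlines from rasterized 3D volumes, so
the pipeline also runs from image volumes rather than centerline tables.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_tortuosity_metrics.py
python analysis/03_cluster_detection.py
python analysis/04_reader_study.py
python analysis/05_roc_summary.py
python analysis/06_segmentation_recovery.py
```

Output from a run at seed 1 (truncated):

```
mean_soam: tumor 3.44 +/- 0.23 vs control 3.07 +/- 0.21 rad/mm (Wilcoxon p = 2.2e-05)
mean_dm:   tumor 1.98 +/- 0.87 vs control 1.47 +/- 0.10  (Wilcoxon p = 0.53)
max cluster size: tumor 32.1 +/- 22.7 vs control 5.8 +/- 1.3
cutoff 8 vessels: sensitivity 0.935, specificity 0.941
Kendall's W = 0.729 across 7 readers
pooled reader AUC = 0.786 (95% CI 0.643-0.910)
ROC regression: beta = 0.308 per mm (bootstrap SE 0.125)
Max cluster size: AUC 0.966   Mean SOAM: AUC 0.875   Mean DM: AUC 0.556
```

Reading: image-level mean SOAM separates tumors from controls (higher
turning density in neovasculature) while mean DM does not; the spatial
clustering classifier is far stronger than either image mean, because it
keys on the localized knot of tortuous vessels instead of a whole-image
average that dilutes small tumors. Reader discrimination improves with
tumor diameter (positive β), mirroring the classifier's size–sensitivity
relation.

The same pipeline is scriptable via the CLI (`angioquant simulate --seed 1
--outdir results/run1`, plus `volumes`, `centerlines`, `all` subcommands)
or the library (`angioquant.run_pipeline`).

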