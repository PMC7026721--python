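"""Density-based detection of tumors from spatial clusters of tortuous vessels.

Selects vessels with SOAM above 3.5 rad/mm, clusters their centroids with
DBSCAN (min_pts = 4, eps = 27 resampling-grid units = 1.35 mm), classifies
each image by a maximum-cluster-size cutoff of 8 vessels, and regresses
maximum cluster size on tumor diameter. Writes cluster assignments and
per-image cluster metrics.
"""

from pathlib import Path

import pandas as pd

from angioquant import io as aio
from angioquant.pipeline import analyze_cohort, images_from_centerlines
from angioquant.stats import size_metric_regression

OUTDIR = Path("results/analysis")


def main() -> None:
    manifest = aio.read_manifest(OUTDIR / "manifest.csv")
    images = images_from_centerlines(
        aio.read_centerlines(OUTDIR / "centerlines.csv"), manifest, 0.05
    )
    per_image, assignments = analyze_cohort(images)
    per_image.to_csv(OUTDIR / "per_image_metrics.csv", index=False)

    rows = []
    for img_id, cres in assignments.items():
        for vid, lab in zip(cres.vessel_ids, cres.labels):
            rows.append({"image_id": img_id, "vessel_id": vid,
                         "cluster_id": "noise" if lab < 0 else int(lab)})
    pd.DataFrame(rows).to_csv(OUTDIR / "cluster_assignments.csv", index=False)

    tum = per_image[per_image.label == "tumor"]
    ctl = per_image[per_image.label == "control"]
    print(f"max cluster size: tumor {tum.max_cluster_size.mean():.1f} +/- "
          f"{tum.max_cluster_size.std():.1f} vs control "
          f"{ctl.max_cluster_size.mean():.1f} +/- {ctl.max_cluster_size.std():.1f}")
    sens = (tum.max_cluster_size >= 8).mean()
    spec = (ctl.max_cluster_size < 8).mean()
    print(f"cutoff 8 vessels: sensitivity {sens:.3f}, specificity {spec:.3f}")
    slope, intercept, r2, p = size_metric_regression(tum.diameter_mm, tum.max_cluster_size)
    print(f"max cluster size vs diameter: slope {slope:.1f} vessels/mm, "
          f"R^2 = {r2:.2f}, p = {p:.2g}")


if __name__ == "__main__":
    main()
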