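"""Per-vessel tortuosity metrics and the tumor-vs-control group comparison.

Reads the centerlines written by 01_simulate_cohort.py, resamples each
centerline to 50 um, computes the distance metric (DM) and sum-of-angles
metric (SOAM), summarizes each image by its mean metrics, and compares the
groups with the Wilcoxon rank-sum test. Writes per-vessel and per-image
tables.
"""

from pathlib import Path

import pandas as pd

from angioquant import io as aio
from angioquant.pipeline import images_from_centerlines
from angioquant.tortuosity import compare_groups, summarize_image

OUTDIR = Path("results/analysis")


def main() -> None:
    manifest = aio.read_manifest(OUTDIR / "manifest.csv")
    images = images_from_centerlines(
        aio.read_centerlines(OUTDIR / "centerlines.csv"), manifest, 0.05
    )

    vessel_rows, image_rows = [], []
    for rec in images:
        for v in rec.vessels:
            vessel_rows.append({
                "image_id": rec.image_id, "vessel_id": v.vessel_id,
                "n_points": v.centerline.n, "length_mm": v.length_mm,
                "dm": v.dm, "soam": v.soam,
                "centroid_x": v.centroid[0], "centroid_y": v.centroid[1],
                "centroid_z": v.centroid[2],
            })
        s = summarize_image(rec.vessels, rec.image_id)
        image_rows.append({
            "image_id": rec.image_id, "label": rec.label,
            "diameter_mm": rec.diameter_mm, "mean_dm": s.mean_dm,
            "mean_soam": s.mean_soam, "n_vessels": s.n_vessels,
        })
    pd.DataFrame(vessel_rows).to_csv(OUTDIR / "per_vessel_metrics.csv", index=False)
    per_image = pd.DataFrame(image_rows)
    per_image.to_csv(OUTDIR / "image_summaries.csv", index=False)

    tum = per_image[per_image.label == "tumor"]
    ctl = per_image[per_image.label == "control"]
    for metric in ("mean_soam", "mean_dm"):
        _, p = compare_groups(tum[metric], ctl[metric])
        unit = "rad/mm" if metric == "mean_soam" else ""
        print(f"{metric}: tumor {tum[metric].mean():.2f} +/- {tum[metric].std():.2f} "
              f"vs control {ctl[metric].mean():.2f} +/- {ctl[metric].std():.2f} {unit}"
              f" (Wilcoxon p = {p:.2g})")


if __name__ == "__main__":
    main()
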