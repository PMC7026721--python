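"""End-to-end pipeline: simulate -> (rasterize/segment) -> tortuosity -> cluster -> stats.

The pipeline consumes either synthetic cohorts, image volumes, or centerline
tables, and produces the analysis artifacts as CSV/JSON next to a resolved
copy of its configuration. Every stage is a thin call into the library
modules; a single global seed expands deterministically into per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .clustering import ClusterConfig, classify_image, cluster_image
from .imaging import ExtractionConfig, extract_vessels, interpolate_isotropic, rasterize_vessels
from .records import ImageRecord, measure_vessel
from .stats import (
    ReaderPanel,
    auc_mann_whitney,
    bootstrap_ci,
    kendalls_w,
    optimal_cutoff,
    predicted_roc,
    roc_curve,
    roc_regression,
    size_metric_regression,
)
from .synth import ReaderModelParams, SynthParams, generate_cohort, simulate_reader_scores
from .tortuosity import DEFAULT_SPACING_MM, compare_groups, summarize_image

__all__ = ["PipelineConfig", "run_pipeline", "analyze_cohort", "cohort_statistics", "images_from_centerlines"]

log = logging.getLogger("angioquant")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved parameters for every stage; round-trips losslessly through YAML."""

    synth: SynthParams = field(default_factory=SynthParams)
    reader: ReaderModelParams = field(default_factory=ReaderModelParams)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    resample_spacing_mm: float = DEFAULT_SPACING_MM
    cluster_cutoff: int = 8
    n_boot: int = 1000
    raster_spacing_mm: float = 0.1
    raster_radius_mm: float = 0.15
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.resample_spacing_mm <= 0:
            raise ValueError("resample spacing must be positive")
        if self.cluster_cutoff < 1:
            raise ValueError("cluster cutoff must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("synth", SynthParams), ("reader", ReaderModelParams),
                         ("cluster", ClusterConfig)):
            if key in d and isinstance(d[key], dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()
                }
                d[key] = typ(**sub)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ["synth", "reader", "bootstrap", "raster"]
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def analyze_cohort(images, cluster_cfg: ClusterConfig | None = None, cutoff: int = 8):
    """Per-image tortuosity summaries, cluster metrics and classification.

    Returns ``(DataFrame, assignments)`` where the frame has one row per image
    (mean DM/SOAM, max cluster size, counts, prediction) and ``assignments``
    maps image_id to the per-candidate-vessel cluster labels.
    """
    cluster_cfg = cluster_cfg or ClusterConfig()
    rows, assignments = [], {}
    for rec in images:
        summ = summarize_image(rec.vessels, rec.image_id)
        cres = cluster_image(rec.vessels, cluster_cfg)
        assignments[rec.image_id] = cres
        rows.append(
            {
                "image_id": rec.image_id,
                "label": rec.label,
                "diameter_mm": rec.diameter_mm,
                "mean_dm": summ.mean_dm,
                "mean_soam": summ.mean_soam,
                "n_vessels": summ.n_vessels,
                "max_cluster_size": cres.max_cluster_size,
                "n_clusters": cres.n_clusters,
                "n_clustered": cres.n_clustered,
                "prediction": classify_image(cres, cutoff),
            }
        )
    return pd.DataFrame(rows), assignments


def cohort_statistics(
    per_image: pd.DataFrame,
    panel: ReaderPanel | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Group comparisons, ROC analyses and (optionally) reader-study statistics."""
    labels = (per_image["label"] == "tumor").to_numpy()
    out: dict = {}

    for metric in ("max_cluster_size", "mean_soam", "mean_dm"):
        values = per_image[metric].to_numpy(float)
        curve = roc_curve(values, labels)
        ci = bootstrap_ci(
            lambda v, l: auc_mann_whitney(v, l), values, labels, n_boot=n_boot, seed=seed
        )
        thr, sens, spec = optimal_cutoff(curve, "youden")
        out[metric] = {
            "auc": curve.auc,
            "auc_ci": ci,
            "youden_threshold": thr,
            "sensitivity": sens,
            "specificity": spec,
        }
        w, p = compare_groups(values[labels], values[~labels])
        out[metric]["wilcoxon_statistic"] = w
        out[metric]["wilcoxon_p"] = p
        out[metric]["tumor_mean"] = float(values[labels].mean())
        out[metric]["tumor_sd"] = float(values[labels].std(ddof=1))
        out[metric]["control_mean"] = float(values[~labels].mean())
        out[metric]["control_sd"] = float(values[~labels].std(ddof=1))

    tum = per_image[per_image["label"] == "tumor"]
    if len(tum) >= 3 and tum["diameter_mm"].var() > 0:
        slope, intercept, r2, p = size_metric_regression(
            tum["diameter_mm"], tum["max_cluster_size"]
        )
        out["size_regression"] = {
            "slope": slope, "intercept": intercept, "r_squared": r2, "p": p
        }

    if panel is not None:
        out["kendalls_w"] = kendalls_w(panel.scores)
        pooled = panel.scores.mean(axis=0)
        curve = roc_curve(pooled, panel.labels)
        ci = bootstrap_ci(
            lambda v, l: auc_mann_whitney(v, l),
            pooled, panel.labels, n_boot=n_boot, seed=seed,
        )
        thr, sens, spec = optimal_cutoff(curve, "youden")
        out["reader"] = {
            "auc": curve.auc, "auc_ci": ci,
            "youden_threshold": thr, "sensitivity": sens, "specificity": spec,
        }
        fit = roc_regression(panel, n_boot=n_boot, seed=seed)
        out["roc_regression"] = {
            "alpha0": fit.alpha0.tolist(),
            "alpha1": fit.alpha1,
            "beta": fit.beta,
            "beta_se": None if fit.bootstrap_se is None else fit.bootstrap_se["beta"],
            "beta_ci": None if fit.ci is None else fit.ci["beta"],
        }
        diam = panel.diameters[panel.labels]
        quartiles = np.quantile(diam, [0.25, 0.5, 0.75])
        out["predicted_auc_by_diameter"] = {
            f"q{q}": predicted_roc(fit, float(x)).auc
            for q, x in zip((25, 50, 75), quartiles)
        }
        operating = {}
        for q, x in zip((25, 50, 75), quartiles):
            curve_x = predicted_roc(fit, float(x))
            _, sens_at_spec, _ = optimal_cutoff(
                _finite(curve_x), "fix_spec", 0.9
            )
            _, _, spec_at_sens = optimal_cutoff(
                _finite(curve_x), "fix_sens", 0.9
            )
            operating[f"q{q}"] = {
                "sens_at_spec90": sens_at_spec, "spec_at_sens90": spec_at_sens
            }
        out["operating_points_by_diameter"] = operating
    return out


def _finite(curve):
    """Give a model ROC curve pseudo-thresholds so operating-point search works."""
    from .stats import ROCCurve

    return ROCCurve(
        thresholds=np.arange(curve.fpr.size, dtype=float)[::-1],
        fpr=curve.fpr, tpr=curve.tpr, auc=curve.auc,
    )


def images_from_centerlines(centerlines: dict, manifest: pd.DataFrame, spacing: float):
    images = []
    for _, row in manifest.iterrows():
        img_id = str(row["image_id"])
        vessels = tuple(
            measure_vessel(vid, cl, spacing)
            for vid, cl in sorted(centerlines.get(img_id, {}).items())
        )
        diam = row.get("diameter_mm")
        images.append(
            ImageRecord(
                image_id=img_id,
                label=str(row["label"]),
                vessels=vessels,
                diameter_mm=None if pd.isna(diam) else float(diam),
            )
        )
    return images


def run_pipeline(cfg: PipelineConfig, entry_point: str = "simulate") -> dict:
    """Execute the pipeline from one of three entry points.

    ``simulate`` generates the synthetic cohort; ``volumes`` additionally
    rasterizes each image and re-extracts vessels from the volumes (slow;
    meant for reduced grids); ``centerlines`` reads previously written
    centerline + manifest CSVs from the output directory. All stages write
    their artifacts under ``cfg.outdir`` and the resolved config is saved
    alongside.
    """
    if entry_point not in ("simulate", "volumes", "centerlines"):
        raise ValueError(f"unknown entry point {entry_point!r}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    seeds = _stage_seeds(cfg.seed)
    t0 = time.time()

    panel = None
    if entry_point == "centerlines":
        manifest_path = outdir / "manifest.csv"
        cl_path = outdir / "centerlines.csv"
        for p in (manifest_path, cl_path):
            if not p.exists():
                raise FileNotFoundError(f"stage 'centerlines' needs missing artifact {p}")
        manifest = aio.read_manifest(manifest_path)
        images = images_from_centerlines(
            aio.read_centerlines(cl_path), manifest, cfg.resample_spacing_mm
        )
        panel_path = outdir / "reader_panel.csv"
        if panel_path.exists():
            panel = aio.read_reader_panel(panel_path, manifest)
    else:
        synth = dataclasses.replace(cfg.synth, seed=seeds["synth"])
        images = generate_cohort(synth)
        log.info("simulate: %d images in %.1fs", len(images), time.time() - t0)
        aio.write_manifest(outdir / "manifest.csv", images)
        aio.write_centerlines(outdir / "centerlines.csv", images)
        aio.write_ground_truth(outdir / "ground_truth.json", images)
        reader = dataclasses.replace(cfg.reader, seed=seeds["reader"])
        panel = simulate_reader_scores(images, reader)
        aio.write_reader_panel(
            outdir / "reader_panel.csv", panel, [r.image_id for r in images]
        )
        if entry_point == "volumes":
            images = _resegment_from_volumes(cfg, images, seeds["raster"])

    per_image, assignments = analyze_cohort(images, cfg.cluster, cfg.cluster_cutoff)
    per_image.to_csv(outdir / "per_image_metrics.csv", index=False)
    _write_vessel_table(outdir / "per_vessel_metrics.csv", images)
    _write_assignments(outdir / "cluster_assignments.csv", assignments)
    stats = cohort_statistics(per_image, panel, cfg.n_boot, seeds["bootstrap"])
    with open(outdir / "statistics.yaml", "w") as fh:
        yaml.safe_dump(_plain(stats), fh, sort_keys=True)
    log.info("pipeline (%s) finished in %.1fs", entry_point, time.time() - t0)
    return {"images": images, "per_image": per_image, "panel": panel, "stats": stats}


def _resegment_from_volumes(cfg: PipelineConfig, images, seed: int):
    rng = np.random.default_rng(seed)
    out = []
    fov = np.asarray(cfg.synth.field_of_view)
    shape = tuple(int(round(f / cfg.raster_spacing_mm)) + 1 for f in fov)
    for rec in images:
        vol = rasterize_vessels(
            [v.centerline for v in rec.vessels],
            cfg.raster_radius_mm,
            shape,
            (cfg.raster_spacing_mm,) * 3,
            blur_mm=cfg.raster_spacing_mm / 2,
            noise_sd=0.02,
            seed=rng,
        )
        vol = interpolate_isotropic(vol, cfg.raster_spacing_mm)
        vessels = extract_vessels(
            vol, ExtractionConfig(resample_spacing_mm=cfg.resample_spacing_mm)
        )
        out.append(dataclasses.replace(rec, vessels=tuple(vessels), volume=None))
    return out


def _write_vessel_table(path, images) -> None:
    rows = []
    for rec in images:
        for v in rec.vessels:
            rows.append(
                {
                    "image_id": rec.image_id,
                    "vessel_id": v.vessel_id,
                    "n_points": v.centerline.n,
                    "length_mm": v.length_mm,
                    "dm": v.dm,
                    "soam": v.soam,
                    "centroid_x": v.centroid[0],
                    "centroid_y": v.centroid[1],
                    "centroid_z": v.centroid[2],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_assignments(path, assignments) -> None:
    rows = []
    for img_id, cres in assignments.items():
        for vid, lab in zip(cres.vessel_ids, cres.labels):
            rows.append({"image_id": img_id, "vessel_id": vid,
                         "cluster_id": "noise" if lab < 0 else int(lab)})
    pd.DataFrame(rows, columns=["image_id", "vessel_id", "cluster_id"]).to_csv(
        path, index=False
    )


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
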