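"""File formats: centerline tables, cohort manifests, reader panels, volumes.

Tables are RFC-4180 CSV (UTF-8, '.' decimal); all lengths are millimeters.
Centerline CSV columns: image_id, vessel_id, point_index, x_mm, y_mm, z_mm.
Volumes round-trip as multi-page TIFF (spacing in a sidecar YAML) or NIfTI
(spacing in the affine).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imaging import ImageVolume
from .records import ImageRecord
from .stats import ReaderPanel
from .tortuosity import Centerline

__all__ = [
    "write_centerlines",
    "read_centerlines",
    "write_centerlines_json",
    "read_centerlines_json",
    "write_manifest",
    "read_manifest",
    "write_reader_panel",
    "read_reader_panel",
    "write_ground_truth",
    "read_ground_truth",
    "write_volume",
    "read_volume",
]

_CL_COLUMNS = ["image_id", "vessel_id", "point_index", "x_mm", "y_mm", "z_mm"]


def write_centerlines(path, images) -> None:
    """Write per-image vessel centerlines as a long-format CSV."""
    rows = []
    for rec in images:
        for v in rec.vessels:
            pts = v.centerline.points
            for i in range(pts.shape[0]):
                rows.append((rec.image_id, v.vessel_id, i, *pts[i]))
    pd.DataFrame(rows, columns=_CL_COLUMNS).to_csv(path, index=False, float_format="%.9f")


def read_centerlines(path) -> dict:
    """Read a centerline CSV; returns {image_id: {vessel_id: Centerline}}.

    Rows may appear in any order; points are re-ordered by point_index.
    Raises a parse error naming the offending location for missing columns or
    non-contiguous point indices. Empty files yield an empty mapping with a
    warning.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty centerline file", stacklevel=2)
        return {}
    missing = [c for c in _CL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict = {}
    for (img, vid), grp in df.groupby(["image_id", "vessel_id"], sort=True):
        grp = grp.sort_values("point_index")
        idx = grp["point_index"].to_numpy()
        if not np.array_equal(idx, np.arange(idx.size)):
            first_bad = int(idx[np.flatnonzero(idx != np.arange(idx.size))[0]])
            raise ValueError(
                f"{path}: vessel {vid!r} of image {img!r} has non-contiguous "
                f"point_index near {first_bad}"
            )
        pts = grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        out.setdefault(str(img), {})[int(vid)] = Centerline(pts)
    return out


def write_centerlines_json(path, images) -> None:
    payload = {
        rec.image_id: {
            str(v.vessel_id): v.centerline.points.tolist() for v in rec.vessels
        }
        for rec in images
    }
    Path(path).write_text(json.dumps(payload))


def read_centerlines_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {
        img: {int(vid): Centerline(np.asarray(pts)) for vid, pts in vs.items()}
        for img, vs in payload.items()
    }


def write_manifest(path, images) -> None:
    """Cohort manifest CSV: id, label, diameter_mm, seed."""
    rows = [
        (rec.image_id, rec.label, rec.diameter_mm, rec.seed) for rec in images
    ]
    pd.DataFrame(rows, columns=["image_id", "label", "diameter_mm", "seed"]).to_csv(
        path, index=False
    )


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"image_id", "label"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(needed)}")
    return df


def write_reader_panel(path, panel: ReaderPanel, image_ids) -> None:
    """Reader-by-image score matrix CSV (readers as rows)."""
    df = pd.DataFrame(panel.scores, index=list(panel.reader_ids), columns=list(image_ids))
    df.index.name = "reader"
    df.to_csv(path)


def read_reader_panel(path, manifest: pd.DataFrame) -> ReaderPanel:
    df = pd.read_csv(path, index_col="reader")
    order = [str(i) for i in manifest["image_id"]]
    df = df[order]
    labels = (manifest["label"] == "tumor").to_numpy()
    diam = manifest.get("diameter_mm", pd.Series(np.nan, index=manifest.index)).to_numpy(float)
    return ReaderPanel(
        scores=df.to_numpy(), labels=labels, diameters=diam, reader_ids=tuple(df.index)
    )


def write_ground_truth(path, images) -> None:
    payload = {}
    for rec in images:
        payload[rec.image_id] = {
            "label": rec.label,
            "diameter_mm": rec.diameter_mm,
            "tumor_center": None if rec.tumor_center is None else list(rec.tumor_center),
            "membership": {str(k): v for k, v in rec.truth_membership.items()},
        }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_volume(path, v: ImageVolume) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or multi-page TIFF + YAML sidecar."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        affine = np.diag([*v.spacing, 1.0])
        affine[:3, 3] = v.origin
        nib.save(nib.Nifti1Image(v.data.astype(np.float32), affine), str(path))
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, v.data.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".yaml")
        sidecar.write_text(
            yaml.safe_dump({"spacing_mm": list(v.spacing), "origin_mm": list(v.origin),
                            "axes": "axial,lateral,elevation"})
        )
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def read_volume(path) -> ImageVolume:
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(np.abs(np.diag(affine)[:3]))
        origin = tuple(affine[:3, 3])
        return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing, origin)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path).astype(float)
        sidecar = path.with_suffix(path.suffix + ".yaml")
        meta = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
        spacing = tuple(meta.get("spacing_mm", (1.0, 1.0, 1.0)))
        origin = tuple(meta.get("origin_mm", (0.0, 0.0, 0.0)))
        return ImageVolume(data, spacing, origin)
    raise ValueError(f"unsupported volume format: {path.suffix}")
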