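"""Density-based spatial clustering of tortuous vessels.

Tumor neovasculature forms spatially compact groups of high-tortuosity
vessels; healthy vasculature does not. The detector therefore (1) selects
vessels above a SOAM threshold, (2) clusters their centerline centroids with
DBSCAN, and (3) classifies an image as tumor when the largest cluster reaches
a minimum size (default 8 vessels).

Coordinates fed to DBSCAN are expressed in units of the centerline resampling
grid (50 um), so the default neighborhood radius eps = 27 corresponds to
1.35 mm; the unit conversion happens in :func:`vessel_features` and nowhere
else. DBSCAN is implemented here (rather than via scikit-learn) because the
border-point rule must be deterministic: a border point joins the cluster of
its nearest core point, ties broken toward the lowest point index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .tortuosity import DEFAULT_SPACING_MM

__all__ = [
    "ClusterConfig",
    "ClusterResult",
    "select_tortuous",
    "vessel_features",
    "dbscan",
    "cluster_metrics",
    "classify_image",
    "cluster_image",
]

NOISE = -1


@dataclass(frozen=True)
class ClusterConfig:
    """DBSCAN parameters and the tortuosity selection rule.

    eps is in feature-space units: with the default centroid feature the unit
    is one resampling-grid step (grid_spacing_mm), so eps=27 is 1.35 mm.
    soam_threshold selects candidate vessels by absolute SOAM (rad/mm);
    soam_percentile, if set, overrides it with a cohort-percentile rule.
    """

    min_pts: int = 4
    eps: float = 27.0
    soam_threshold: float = 3.5
    soam_percentile: float | None = None
    grid_spacing_mm: float = DEFAULT_SPACING_MM
    include_tortuosity_features: bool = False
    tortuosity_feature_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.grid_spacing_mm <= 0:
            raise ValueError("grid_spacing_mm must be positive")


@dataclass(frozen=True)
class ClusterResult:
    """DBSCAN labels over the candidate vessels plus derived classifier metrics."""

    labels: np.ndarray = field(repr=False)
    vessel_ids: tuple = ()

    @property
    def cluster_sizes(self) -> np.ndarray:
        lab = self.labels[self.labels != NOISE]
        if lab.size == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(lab)

    @property
    def max_cluster_size(self) -> int:
        sizes = self.cluster_sizes
        return int(sizes.max()) if sizes.size else 0

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_sizes.size)

    @property
    def n_clustered(self) -> int:
        return int((self.labels != NOISE).sum())


def select_tortuous(vessels: Sequence, cfg: ClusterConfig | None = None) -> list:
    """Keep vessels whose SOAM exceeds the configured threshold.

    Default rule is an absolute threshold (3.5 rad/mm, between the typical
    control and tumor group means); ``soam_percentile`` switches to a
    cohort-percentile cut computed over the given vessels.
    """
    cfg = cfg or ClusterConfig()
    usable = [v for v in vessels if getattr(v, "soam", None) is not None]
    if cfg.soam_percentile is not None:
        if not usable:
            return []
        thr = float(np.percentile([v.soam for v in usable], cfg.soam_percentile))
    else:
        thr = cfg.soam_threshold
    return [v for v in usable if v.soam > thr]


def vessel_features(vessels: Sequence, cfg: ClusterConfig | None = None) -> np.ndarray:
    """Per-vessel DBSCAN feature vectors: centroid in resampling-grid units.

    Optionally appends scaled (DM, SOAM) when include_tortuosity_features.
    """
    cfg = cfg or ClusterConfig()
    if not vessels:
        return np.zeros((0, 3))
    feats = np.array([v.centroid for v in vessels], dtype=float) / cfg.grid_spacing_mm
    if cfg.include_tortuosity_features:
        extra = np.array(
            [[v.dm, v.soam] for v in vessels], dtype=float
        ) * cfg.tortuosity_feature_scale
        feats = np.hstack([feats, extra])
    return feats


def dbscan(features, eps: float, min_pts: int) -> np.ndarray:
    """DBSCAN with deterministic labels.

    Core point: at least ``min_pts`` points (self included) within the closed
    Euclidean ball of radius ``eps``. Clusters are connected components of
    core points under eps-adjacency, numbered 0,1,... by the lowest point
    index they contain; each border point (non-core within eps of a core)
    joins the cluster of its nearest core neighbor, ties toward the lowest
    core index. Everything else is noise (-1).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    x = np.asarray(features, dtype=float)
    if x.size == 0:
        return np.zeros(0, dtype=int)
    if x.ndim != 2:
        raise ValueError("features must be a 2D array")
    n = x.shape[0]
    tree = cKDTree(x)
    neighborhoods = tree.query_ball_point(x, eps)
    is_core = np.array([len(nb) >= min_pts for nb in neighborhoods])
    labels = np.full(n, NOISE, dtype=int)

    # union-find over eps-adjacent core points
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in np.flatnonzero(is_core):
        for j in neighborhoods[i]:
            if is_core[j]:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    roots = {}
    for i in np.flatnonzero(is_core):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        labels[i] = roots[r]

    for i in range(n):
        if is_core[i]:
            continue
        core_nb = sorted(j for j in neighborhoods[i] if is_core[j])
        if not core_nb:
            continue
        d = np.linalg.norm(x[core_nb] - x[i], axis=1)
        labels[i] = labels[core_nb[int(np.argmin(d))]]  # argmin ties -> lowest index
    return labels


def cluster_metrics(labels, vessel_ids: Sequence | None = None) -> ClusterResult:
    """Wrap DBSCAN labels into the derived classifier metrics."""
    labels = np.asarray(labels, dtype=int)
    ids = tuple(vessel_ids) if vessel_ids is not None else tuple(range(labels.size))
    return ClusterResult(labels=labels, vessel_ids=ids)


def classify_image(result: ClusterResult, cutoff: int = 8) -> str:
    """Call an image 'tumor' iff its largest cluster has at least ``cutoff`` vessels."""
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    return "tumor" if result.max_cluster_size >= cutoff else "control"


def cluster_image(vessels: Sequence, cfg: ClusterConfig | None = None) -> ClusterResult:
    """Select tortuous vessels, cluster their centroids, return the metrics."""
    cfg = cfg or ClusterConfig()
    candidates = select_tortuous(vessels, cfg)
    feats = vessel_features(candidates, cfg)
    labels = dbscan(feats, cfg.eps, cfg.min_pts) if len(candidates) else np.zeros(0, int)
    return cluster_metrics(labels, [getattr(v, "vessel_id", i) for i, v in enumerate(candidates)])
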