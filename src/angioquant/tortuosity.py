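"""Vessel centerline tortuosity metrics.

A centerline is an ordered polyline p_1..p_n through the middle of a vessel,
coordinates in millimeters. Two tortuosity metrics are computed on centerlines
resampled to uniform arc-length spacing (50 um by default):

* the distance metric (DM) — total path length divided by the endpoint chord
  length, dimensionless, >= 1 with equality iff the polyline is straight;
* the sum-of-angles metric (SOAM) — total turning angle along the path divided
  by the path length, in rad/mm; a discrete total-curvature density, >= 0 with
  equality iff the polyline is straight.

Both metrics are invariant under rigid motions; DM is also invariant under
uniform scaling while SOAM scales as 1/scale. SOAM depends on the sampling
density, which is why metrics are always computed after resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "Centerline",
    "ImageSummary",
    "UndefinedMetricError",
    "resample_centerline",
    "distance_metric",
    "sum_of_angles",
    "summarize_image",
    "compare_groups",
]

DEFAULT_SPACING_MM = 0.05


class UndefinedMetricError(ValueError):
    """A tortuosity metric is undefined for this centerline (e.g. closed loop)."""


@dataclass(frozen=True)
class Centerline:
    """Ordered 3D polyline in mm; at least two points, consecutive points distinct."""

    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"centerline points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive centerline points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def arc_length(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass(frozen=True)
class ImageSummary:
    """Per-image mean tortuosity over vessels with defined metrics."""

    image_id: str
    mean_dm: float
    mean_soam: float
    n_vessels: int


def _as_points(c) -> np.ndarray:
    if isinstance(c, Centerline):
        return c.points
    return Centerline(np.asarray(c, dtype=float)).points


def resample_centerline(c, spacing: float = DEFAULT_SPACING_MM) -> Centerline:
    """Resample a centerline to uniform arc-length spacing by linear interpolation.

    The first point is preserved exactly and the original endpoint is appended,
    so the final interval may be shorter than ``spacing``. A polyline shorter
    than one spacing collapses to its two endpoints.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = _as_points(c)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < spacing:
        return Centerline(np.stack([pts[0], pts[-1]]))
    targets = np.arange(0.0, total, spacing)
    out = np.empty((targets.size, 3))
    for ax in range(3):
        out[:, ax] = np.interp(targets, s, pts[:, ax])
    if total - targets[-1] > 1e-12 * max(total, 1.0):
        out = np.vstack([out, pts[-1]])
    else:
        out[-1] = pts[-1]
    # interpolation can land on duplicate knots; drop zero-length segments
    keep = np.concatenate([[True], np.linalg.norm(np.diff(out, axis=0), axis=1) > 0])
    return Centerline(out[keep])


def distance_metric(c) -> float:
    """DM: path length over endpoint chord length.

    Raises :class:`UndefinedMetricError` for closed loops (coincident
    endpoints), which are excluded from image means by the caller.
    """
    pts = _as_points(c)
    chord = float(np.linalg.norm(pts[0] - pts[-1]))
    if chord == 0.0:
        raise UndefinedMetricError("coincident endpoints: DM undefined for closed loop")
    path = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return path / chord


def sum_of_angles(c) -> float:
    """SOAM: summed turning angles between consecutive point trios over path length.

    For each interior point the angle between the unit segment vectors
    nu_x = p_{x+1} - p_x and nu_{x+1} is taken via arccos of their dot product
    (clamped to [-1, 1] against floating-point overshoot); the sum is divided
    by the total path length in mm. Returns 0.0 for degenerate (< 3 point)
    centerlines.
    """
    pts = _as_points(c)
    if pts.shape[0] < 3:
        return 0.0
    v = np.diff(pts, axis=0)
    u = v / np.linalg.norm(v, axis=1, keepdims=True)
    dots = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    angles = np.arccos(dots)
    path = float(np.linalg.norm(v, axis=1).sum())
    return float(angles.sum() / path)


def summarize_image(vessels, image_id: str = "") -> ImageSummary:
    """Arithmetic mean DM and SOAM over vessels with defined (non-degenerate) metrics.

    ``vessels`` is an iterable of objects with ``dm`` and ``soam`` attributes
    (``dm is None`` marks an undefined metric). Raises if no usable vessel.
    """
    dms, soams = [], []
    for v in vessels:
        if getattr(v, "dm", None) is None or not math.isfinite(v.dm):
            continue
        dms.append(v.dm)
        soams.append(v.soam)
    if not dms:
        raise ValueError(f"image {image_id!r}: no vessels with defined tortuosity metrics")
    return ImageSummary(
        image_id=image_id,
        mean_dm=float(np.mean(dms)),
        mean_soam=float(np.mean(soams)),
        n_vessels=len(dms),
    )


def _ranksum_exact(ranks: np.ndarray, n1: int) -> float:
    """Two-sided exact rank-sum p over all group-1 assignments (midranks).

    Midranks are multiples of 1/2, so doubling makes them integers and the
    null distribution of the rank sum follows from a subset-sum count.
    """
    n = ranks.size
    doubled = np.rint(2 * ranks).astype(int)
    w_obs = int(np.rint(2 * ranks[:n1].sum()))
    max_sum = int(doubled.sum())
    # ways[k, s]: #subsets of size k with doubled-rank sum s
    ways = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in doubled:
        ways[1:, r:] += ways[:-1, :-r or None]
    dist = ways[n1]
    total = dist.sum()
    lo = dist[: w_obs + 1].sum() / total
    hi = dist[w_obs:].sum() / total
    return min(1.0, 2.0 * min(lo, hi))


def compare_groups(tumor_values, control_values, exact_max_n: int = 10):
    """Wilcoxon rank-sum comparison of two groups with midranks for ties.

    Uses exact enumeration of the null when both groups have at most
    ``exact_max_n`` observations, otherwise the normal approximation with tie
    and continuity corrections. Returns ``(statistic, p_two_sided)`` where the
    statistic is the rank sum of the first group.
    """
    x = np.asarray(tumor_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = sps.rankdata(np.concatenate([x, y]))
    n1, n2 = x.size, y.size
    w = float(ranks[:n1].sum())
    if n1 <= exact_max_n and n2 <= exact_max_n:
        return w, _ranksum_exact(ranks, n1)
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return w, 1.0
    diff = w - mean_w
    z = (abs(diff) - 0.5) / math.sqrt(var_w)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return w, min(1.0, float(p))
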