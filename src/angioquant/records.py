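"""Shared record types: vessels and images with their measured quantities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tortuosity import (
    Centerline,
    UndefinedMetricError,
    distance_metric,
    resample_centerline,
    sum_of_angles,
    DEFAULT_SPACING_MM,
)

__all__ = ["VesselRecord", "ImageRecord", "measure_vessel"]


@dataclass(frozen=True)
class VesselRecord:
    """A segmented vessel: centerline plus per-vessel tortuosity and centroid.

    ``dm`` is None when the metric is undefined (closed loop); such vessels
    are excluded from image means and from clustering candidate selection.
    """

    vessel_id: int
    centerline: Centerline = field(repr=False)
    dm: float | None
    soam: float | None
    centroid: np.ndarray = field(repr=False)
    radius_estimate: float | None = None

    @property
    def length_mm(self) -> float:
        return self.centerline.arc_length


@dataclass(frozen=True)
class ImageRecord:
    """One subject's image: vessel set, class label, tumor size, ground truth.

    ``truth_membership`` maps vessel_id -> "cluster" | "background" and, with
    ``tumor_center``, allows recovery tests against the generator's ground
    truth. ``volume`` optionally holds a rasterized intensity volume.
    """

    image_id: str
    label: str  # "tumor" | "control"
    vessels: tuple = field(repr=False, default=())
    diameter_mm: float | None = None
    tumor_center: np.ndarray | None = field(repr=False, default=None)
    truth_membership: dict = field(repr=False, default_factory=dict)
    seed: int | None = None
    volume: object = field(repr=False, default=None)

    @property
    def is_tumor(self) -> bool:
        return self.label == "tumor"


def measure_vessel(
    vessel_id: int,
    centerline: Centerline,
    spacing: float = DEFAULT_SPACING_MM,
    radius_estimate: float | None = None,
) -> VesselRecord:
    """Resample a centerline and fill in DM, SOAM and the centroid.

    Metrics are always computed on the resampled polyline; loops (coincident
    endpoints) get ``dm = soam = None`` and are reported as degenerate.
    """
    rs = resample_centerline(centerline, spacing)
    try:
        dm = distance_metric(rs)
        soam = sum_of_angles(rs)
    except UndefinedMetricError:
        dm = soam = None
    return VesselRecord(
        vessel_id=vessel_id,
        centerline=rs,
        dm=dm,
        soam=soam,
        centroid=rs.centroid,
        radius_estimate=radius_estimate,
    )
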