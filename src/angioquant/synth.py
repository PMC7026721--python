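"""Synthetic cohort generator.

Emulates a contrast-enhanced microvascular imaging study of a murine breast
cancer model: control images contain sparse, smooth background vessels
(grouped into loose vascular bundles plus one compact benign confluence of
mildly tortuous vessels), while tumor images additionally contain a spatially
localized cluster of high-tortuosity neovessels confined to a sphere of the
tumor's diameter. Tumor diameters follow a truncated lognormal skewed toward
small tumors, and a simulated panel of readers scores each image on an
ordinal 1-6 malignancy scale through a latent-probit model.

Every generator is deterministic under its seed; a cohort seed expands to
per-image child seeds through ``numpy.random.SeedSequence`` spawning, so any
single image can be regenerated independently.

Vessel waviness mechanism
-------------------------
A centerline grows by fixed arc-length steps. At each step the heading is
rotated by an angle |N(0, sigma)| about a perpendicular axis whose azimuth
drifts slowly (AR(1)), producing smooth curves. Because the turning angle
between consecutive segments equals the applied rotation, the expected SOAM
is exactly the target when sigma = target * step * sqrt(pi/2), i.e. the
amplitude-to-SOAM calibration is closed-form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .records import ImageRecord, VesselRecord, measure_vessel
from .stats import ReaderPanel
from .tortuosity import Centerline, DEFAULT_SPACING_MM

__all__ = [
    "SynthParams",
    "ReaderModelParams",
    "make_centerline",
    "sample_diameters",
    "generate_image",
    "generate_cohort",
    "simulate_reader_scores",
    "simulate_binormal_panel",
]


@dataclass(frozen=True)
class SynthParams:
    """Study-design parameters of the synthetic cohort.

    Tortuosity targets are image-level mean SOAM values (rad/mm); diameters
    are drawn from a lognormal (median ~2.3 mm, mean ~3.1 mm) truncated to
    [0.8, 8.2] mm. The tortuous-cluster vessel count scales with tumor
    diameter with lognormal noise, calibrated so its cohort mean/SD land near
    34 +/- 33 vessels.
    """

    n_tumor: int = 31
    n_control: int = 17
    vessels_per_image: tuple = (40, 60)
    field_of_view: tuple = (25.0, 25.0, 25.0)
    control_tortuosity_target: float = 3.09  # image-level mean SOAM, rad/mm
    tumor_tortuosity_target: float = 3.61
    cluster_vessel_soam: float = 4.4  # per-vessel target for tumor neovessels
    # tortuous-vessel recruitment: count ~ coeff * d^exponent * lognormal noise;
    # the sublinear exponent reflects the weak size dependence of cluster size
    cluster_count_coeff: float = 20.0
    cluster_count_exponent: float = 0.7
    cluster_count_sigma: float = 0.55
    diameter_log_mean: float = math.log(2.3)
    diameter_log_sigma: float = 0.772
    diameter_bounds: tuple = (0.8, 8.2)
    n_bundles: int = 7
    bundle_sd_mm: float = 0.25
    knot_mean_count: float = 5.4  # benign confluence emulating control clusters
    knot_sd_count: float = 1.4
    knot_soam: float = 4.5
    vessel_soam_jitter: float = 0.35
    image_soam_jitter: float = 0.25
    # bending-axis persistence per vessel class: a slowly drifting axis makes
    # coiled paths (high DM), a fast one makes jittery-but-straight paths
    background_axis_drift: float = 1.5
    knot_axis_drift: float = 1.0
    cluster_axis_drift: float = 0.2
    step_mm: float = DEFAULT_SPACING_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_control < 1:
            raise ValueError("counts must be >= 1")
        if self.control_tortuosity_target <= 0 or self.tumor_tortuosity_target <= 0:
            raise ValueError("tortuosity targets must be positive")
        lo, hi = self.diameter_bounds
        if not (0 < lo < hi):
            raise ValueError("diameter bounds must satisfy 0 < lo < hi")


@dataclass(frozen=True)
class ReaderModelParams:
    """Latent-probit reader panel: reader bias + class and diameter effects.

    latent = bias_k + (class_separation + diameter_effect * diameter) * 1{tumor}
             + image effect + reader noise, discretized by the strictly
    increasing cutpoints into ordinal scores 1-6. The image effect (shared
    across readers) models per-image vascular visibility and drives reader
    concordance; reader-specific intercepts only (no reader slopes).
    image_effect_sd and noise_sd default to quadrature-sum 1 so the marginal
    latent noise is standard.
    """

    n_readers: int = 7
    reader_bias_sd: float = 0.25
    diameter_effect: float = 0.35  # latent units per mm
    class_separation: float = 0.2
    image_effect_sd: float = 0.8
    noise_sd: float = 0.6
    cutpoints: tuple = (-0.6, 0.35, 1.0, 1.7, 2.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_readers < 2:
            raise ValueError("need at least 2 readers")
        c = np.asarray(self.cutpoints, dtype=float)
        if c.size != 5 or np.any(np.diff(c) <= 0):
            raise ValueError("cutpoints must be 5 strictly increasing thresholds")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


def _perpendicular(h: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, h) * h
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


def make_centerline(
    start,
    direction,
    length: float,
    tortuosity_target: float,
    step: float = DEFAULT_SPACING_MM,
    seed=None,
    axis_drift: float = 0.6,
) -> Centerline:
    """Grow a centerline with expected SOAM equal to ``tortuosity_target``.

    ``seed`` may be an int or a Generator. With target 0 the result is exactly
    collinear. ``axis_drift`` is the SD (rad) of the per-step azimuthal drift
    of the bending axis; it shapes smoothness but not the expected SOAM.
    """
    if step <= 0 or length <= 0:
        raise ValueError("step and length must be positive")
    if length < 3 * step:
        raise ValueError("length must be at least 3 steps")
    if tortuosity_target < 0:
        raise ValueError("tortuosity target must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(round(length / step))
    h = _unit(np.asarray(direction, dtype=float))
    pts = np.empty((n_steps + 1, 3))
    pts[0] = np.asarray(start, dtype=float)
    if tortuosity_target == 0.0:
        for i in range(n_steps):
            pts[i + 1] = pts[i] + step * h
        return Centerline(pts)
    sigma = tortuosity_target * step * math.sqrt(math.pi / 2.0)
    u = _perpendicular(h, rng)
    for i in range(n_steps):
        theta = abs(rng.normal(0.0, sigma))
        h = h * math.cos(theta) + np.cross(u, h) * math.sin(theta)
        h = _unit(h)
        dphi = rng.normal(0.0, axis_drift)
        u = u * math.cos(dphi) + np.cross(h, u) * math.sin(dphi)
        u = u - np.dot(u, h) * h
        u = _unit(u)
        pts[i + 1] = pts[i] + step * h
    return Centerline(pts)


def sample_diameters(params: SynthParams, n: int, rng) -> np.ndarray:
    """Draw tumor diameters from the truncated lognormal by rejection."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lo, hi = params.diameter_bounds
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(params.diameter_log_mean, params.diameter_log_sigma, 4 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _background_soam_target(params: SynthParams) -> float:
    """Per-vessel background SOAM target making the image-level control mean hit its target.

    Control images mix ~n_bg background vessels with a small benign knot at
    knot_soam; solve the mixture for the background component.
    """
    n_total = float(np.mean(params.vessels_per_image))
    n_knot = params.knot_mean_count
    n_bg = max(n_total - n_knot, 1.0)
    t = (n_total * params.control_tortuosity_target - n_knot * params.knot_soam) / n_bg
    return max(t, 0.5)


def _grow_background(params: SynthParams, rng, start_id: int):
    """Background vasculature: loose parallel bundles plus one compact benign knot."""
    fov = np.asarray(params.field_of_view)
    n_total = int(rng.integers(params.vessels_per_image[0], params.vessels_per_image[1] + 1))
    n_knot = int(np.clip(round(rng.normal(params.knot_mean_count, params.knot_sd_count)), 4, None))
    n_bg = max(n_total - n_knot, 1)
    bg_target = _background_soam_target(params) + rng.normal(0.0, params.image_soam_jitter)

    centers = rng.uniform(1.0, fov - 1.0, size=(params.n_bundles, 3))
    directions = rng.normal(size=(params.n_bundles, 3))
    vessels = []
    vid = start_id
    for _ in range(n_bg):
        b = int(rng.integers(params.n_bundles))
        start = centers[b] + rng.normal(0.0, 2.0, size=3)
        direction = _unit(directions[b] + rng.normal(0.0, 0.5, size=3))
        length = rng.uniform(2.0, 6.0)
        target = max(bg_target + rng.normal(0.0, params.vessel_soam_jitter), 0.1)
        cl = make_centerline(start, direction, length, target, params.step_mm, rng,
                             axis_drift=params.background_axis_drift)
        vessels.append((vid, cl, "background"))
        vid += 1

    knot_center = rng.uniform(3.0, fov - 3.0)
    knot_dir = rng.normal(size=3)
    for _ in range(n_knot):
        start = knot_center + rng.normal(0.0, params.bundle_sd_mm, size=3)
        direction = _unit(knot_dir + rng.normal(0.0, 0.2, size=3))
        length = rng.uniform(1.0, 2.0)
        target = max(params.knot_soam + rng.normal(0.0, 0.15), 0.1)
        cl = make_centerline(start, direction, length, target, params.step_mm, rng,
                             axis_drift=params.knot_axis_drift)
        vessels.append((vid, cl, "background"))
        vid += 1
    return vessels, vid


def generate_image(
    params: SynthParams, label: str, diameter: float | None = None, seed=None
) -> ImageRecord:
    """Generate one synthetic image: background vessels, plus a tumor cluster if labeled.

    Tumor-cluster centerlines start within 0.15 d of the tumor center with arc
    length 0.3 d, so every point lies within d/2 of the center (arc length
    bounds displacement) — containment by construction, no rescaling.
    """
    if label not in ("tumor", "control"):
        raise ValueError(f"label must be 'tumor' or 'control', got {label!r}")
    if label == "tumor":
        if diameter is None:
            raise ValueError("tumor images need a diameter")
        if diameter >= min(params.field_of_view):
            raise ValueError("tumor diameter exceeds the field of view")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw, vid = _grow_background(params, rng, start_id=0)

    tumor_center = None
    if label == "tumor":
        fov = np.asarray(params.field_of_view)
        margin = diameter / 2.0 + 0.5
        tumor_center = rng.uniform(margin, fov - margin)
        mu = math.log(params.cluster_count_coeff * diameter**params.cluster_count_exponent)
        sig = params.cluster_count_sigma
        count = int(max(6, round(math.exp(rng.normal(mu - sig**2 / 2.0, sig)))))
        for _ in range(count):
            offset = rng.normal(size=3)
            offset = offset / np.linalg.norm(offset) * rng.uniform(0, 0.15 * diameter)
            start = tumor_center + offset
            direction = _unit(rng.normal(size=3))
            length = max(0.3 * diameter, 3 * params.step_mm)
            target = max(params.cluster_vessel_soam + rng.normal(0.0, 0.2), 0.5)
            cl = make_centerline(start, direction, length, target, params.step_mm, rng,
                                 axis_drift=params.cluster_axis_drift)
            raw.append((vid, cl, "cluster"))
            vid += 1

    vessels = []
    membership = {}
    for v_id, cl, member in raw:
        vessels.append(measure_vessel(v_id, cl, params.step_mm))
        membership[v_id] = member
    return ImageRecord(
        image_id="",
        label=label,
        vessels=tuple(vessels),
        diameter_mm=diameter,
        tumor_center=tumor_center,
        truth_membership=membership,
    )


def generate_cohort(params: SynthParams) -> list[ImageRecord]:
    """Generate the full cohort (n_tumor + n_control images), reproducibly.

    The cohort seed spawns one child seed per image, stored on the record.
    """
    ss = np.random.SeedSequence(params.seed)
    diam_rng = np.random.default_rng(ss.spawn(1)[0])
    diameters = sample_diameters(params, params.n_tumor, diam_rng)
    children = ss.spawn(params.n_tumor + params.n_control)
    records = []
    for i in range(params.n_tumor):
        child = children[i]
        rec = generate_image(params, "tumor", float(diameters[i]), np.random.default_rng(child))
        records.append(
            ImageRecord(
                image_id=f"T{i + 1:03d}",
                label=rec.label,
                vessels=rec.vessels,
                diameter_mm=rec.diameter_mm,
                tumor_center=rec.tumor_center,
                truth_membership=rec.truth_membership,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        )
    for j in range(params.n_control):
        child = children[params.n_tumor + j]
        rec = generate_image(params, "control", None, np.random.default_rng(child))
        records.append(
            ImageRecord(
                image_id=f"C{j + 1:03d}",
                label=rec.label,
                vessels=rec.vessels,
                truth_membership=rec.truth_membership,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        )
    return records


def simulate_reader_scores(cohort, rp: ReaderModelParams) -> ReaderPanel:
    """Score a cohort with the latent-probit reader panel (ordinal 1-6)."""
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must be nonempty")
    rng = np.random.default_rng(rp.seed)
    labels = np.array([rec.is_tumor for rec in cohort])
    diameters = np.array(
        [rec.diameter_mm if rec.diameter_mm is not None else np.nan for rec in cohort]
    )
    k, n = rp.n_readers, len(cohort)
    bias = rng.normal(0.0, rp.reader_bias_sd, size=k)
    effect = np.where(
        labels, rp.class_separation + rp.diameter_effect * np.nan_to_num(diameters), 0.0
    )
    image_effect = rng.normal(0.0, rp.image_effect_sd, size=n)
    latent = (
        bias[:, None]
        + (effect + image_effect)[None, :]
        + rng.normal(0.0, rp.noise_sd, size=(k, n))
    )
    cut = np.asarray(rp.cutpoints)
    scores = 1 + np.searchsorted(cut, latent).reshape(k, n)
    return ReaderPanel(scores=scores.astype(int), labels=labels, diameters=diameters)


def simulate_binormal_panel(
    n_tumor: int = 31,
    n_control: int = 17,
    n_readers: int = 7,
    beta: float = 0.35,
    class_separation: float = 0.2,
    reader_bias_sd: float = 0.25,
    params: SynthParams | None = None,
    seed=None,
) -> ReaderPanel:
    """Continuous binormal reader panel for ROC-regression recovery studies.

    Latent scores are reported directly (no ordinal discretization), so the
    true ROC model is exactly probit with baseline slope 1 and diameter
    coefficient ``beta``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = params or SynthParams()
    diameters = np.concatenate(
        [sample_diameters(params, n_tumor, rng), np.full(n_control, np.nan)]
    )
    labels = np.concatenate([np.ones(n_tumor, bool), np.zeros(n_control, bool)])
    bias = rng.normal(0.0, reader_bias_sd, size=n_readers)
    effect = np.where(labels, class_separation + beta * np.nan_to_num(diameters), 0.0)
    scores = bias[:, None] + effect[None, :] + rng.normal(size=(n_readers, n_tumor + n_control))
    return ReaderPanel(scores=scores, labels=labels, diameters=diameters)
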