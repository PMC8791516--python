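"""Synthetic superficial-plexus angiograms and eye-level cohorts.

Two generators back the whole pipeline:

* a **capillary-network simulator** producing perturbed-Voronoi vessel meshes
  with a central foveal avascular zone (FAZ), rasterized into 8-bit grayscale
  angiograms with exact ground-truth masks, so the skeleton-density (VSD) and
  caliber (VDI) metrics can be validated against known truth;
* a **cohort simulator** producing eye-level tables (two correlated eyes per
  subject, nested in centers) whose VSD/VDI group distributions and covariate
  prevalences follow the published control / mild / referable-DR group
  statistics.

Severity is expressed through exactly two knobs: capillary *dropout* (lowers
density, hence VSD) and caliber *dilation* (raises VDI).  ``calibrate_preset``
closes the loop by root-finding those knobs until the measured metrics of
rendered images hit a preset's targets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from ._rng import substream
from .metrics import AngiogramImage, quantify, DEFAULT_BINARIZATION

__all__ = [
    "GroupPreset",
    "VesselNetworkTruth",
    "NoiseModel",
    "CohortConfig",
    "GroupCounts",
    "CalibrationError",
    "DEFAULT_PRESETS",
    "COHORT2_PRESETS",
    "generate_capillary_network",
    "rasterize_angiogram",
    "calibrate_preset",
    "generate_cohort",
    "simulate_logistic_cohort",
    "save_angiogram",
]

DEFAULT_IMAGE_SIDE = 245  # 3-mm scan: 245 B-scans x 245 A-scans


class CalibrationError(RuntimeError):
    """Raised when a preset target is outside the simulator's reachable range."""


@dataclass
class GroupPreset:
    """Target VSD/VDI distribution for one severity group plus simulator knobs.

    ``dropout_fraction`` removes that fraction of network edges (capillary
    loss); ``dilation_factor`` scales all vessel calibers.  The targets are
    dimensionless (VSD) and pixels (VDI); knobs are mapped onto the targets by
    :func:`calibrate_preset`.
    """

    name: str
    target_vsd_mean: float
    target_vsd_sd: float
    target_vdi_mean: float
    target_vdi_sd: float
    dropout_fraction: float = 0.1
    dilation_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.dilation_factor <= 0:
            raise ValueError("dilation_factor must be positive")


#: Published Cohort-1 group distributions (VSD mean[SD], VDI mean[SD]).
DEFAULT_PRESETS = {
    "control": GroupPreset("control", 0.153, 0.006, 2.90, 0.05),
    "mild": GroupPreset("mild", 0.146, 0.010, 2.92, 0.08),
    "referable": GroupPreset("referable", 0.131, 0.012, 3.01, 0.11),
}

#: Published Cohort-2 (screening-clinic) group distributions.
COHORT2_PRESETS = {
    "mild": GroupPreset("mild", 0.149, 0.007, 2.93, 0.06),
    "referable": GroupPreset("referable", 0.135, 0.014, 3.00, 0.09),
}


@dataclass
class VesselNetworkTruth:
    """Ground-truth vessel network for one synthetic angiogram.

    ``segments`` are polyline centerlines in pixel coordinates (row, col);
    ``widths`` the per-segment caliber in pixels.  ``true_skeleton_pixels``
    and ``true_mean_width`` are the rasterized-centerline pixel count and the
    length-weighted mean caliber.
    """

    segments: list
    widths: list
    faz_radius: float
    image_side: int
    true_skeleton_pixels: int
    true_mean_width: float

    def centerline_mask(self) -> np.ndarray:
        """Rasterized centerline (the metric ground truth for the skeleton)."""
        mask, _ = _raster_centerlines(self.segments, self.widths, self.image_side)
        return mask


@dataclass
class NoiseModel:
    """Additive image-noise parameters for the rasterizer (gray levels)."""

    speckle_sd: float = 14.0
    background_level: float = 28.0
    vessel_level: float = 200.0

    def __post_init__(self) -> None:
        if self.speckle_sd < 0 or self.background_level < 0:
            raise ValueError("noise parameters must be non-negative")


# ---------------------------------------------------------------------------
# geometry helpers


def _clip_to_box(p0, p1, lo, hi):
    """Liang-Barsky clip of segment p0-p1 to the square [lo, hi]^2."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for axis in (0, 1):
        if d[axis] == 0:
            if not (lo <= p0[axis] <= hi):
                return None
            continue
        ta = (lo - p0[axis]) / d[axis]
        tb = (hi - p0[axis]) / d[axis]
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
    if t0 >= t1:
        return None
    return p0 + t0 * d, p0 + t1 * d


def _clip_outside_circle(p0, p1, center, radius):
    """Parts of segment p0-p1 lying outside the disk; list of 0-2 segments."""
    d = p1 - p0
    f = p0 - center
    a = float(d @ d)
    if a == 0:
        return []
    b = 2.0 * float(f @ d)
    c = float(f @ f) - radius * radius
    disc = b * b - 4 * a * c
    if disc <= 0:  # no crossing: fully inside or fully outside
        return [] if c < 0 else [(p0, p1)]
    s = math.sqrt(disc)
    t_in, t_out = (-b - s) / (2 * a), (-b + s) / (2 * a)
    pieces = []
    if t_in > 0:
        pieces.append((p0, p0 + min(t_in, 1.0) * d))
    if t_out < 1:
        pieces.append((p0 + max(t_out, 0.0) * d, p1))
    return [(q0, q1) for q0, q1 in pieces if float((q1 - q0) @ (q1 - q0)) > 1.0]


def _raster_centerlines(segments, widths, side, scale: int = 1):
    """Rasterize polyline centerlines at ``scale``x resolution.

    Returns ``(bool centerline mask, radius map)`` on the scaled grid; the
    radius map holds, at each centerline pixel, the half-width (in scaled
    pixels) of the widest segment passing through it, used by the mask
    rasterizer's distance threshold.
    """
    n = side * scale
    mask = np.zeros((n, n), dtype=bool)
    radius = np.zeros((n, n), dtype=float)
    off = (scale - 1) / 2.0  # center of the original pixel in scaled coords
    p0s, p1s, rads = [], [], []
    for seg, w in zip(segments, widths):
        pts = np.asarray(seg, dtype=float) * scale + off
        r = max((scale * w - 1.0) / 2.0, 0.0)
        p0s.append(pts[:-1])
        p1s.append(pts[1:])
        rads.append(np.full(len(pts) - 1, r))
    if not p0s:
        return mask, radius
    p0 = np.concatenate(p0s)
    p1 = np.concatenate(p1s)
    rad = np.concatenate(rads)
    # dense sampling at ~0.4 px steps, vectorized over all pieces at once
    lengths = np.hypot(*(p1 - p0).T)
    steps = np.maximum(np.ceil(lengths / 0.4).astype(int) + 1, 2)
    total = int(steps.sum())
    piece = np.repeat(np.arange(len(steps)), steps)
    j = np.arange(total) - np.repeat(np.cumsum(steps) - steps, steps)
    t = j / (steps[piece] - 1)
    pts = p0[piece] * (1 - t[:, None]) + p1[piece] * t[:, None]
    ij = np.clip(np.round(pts).astype(int), 0, n - 1)
    flat = ij[:, 0] * n + ij[:, 1]
    mask.ravel()[flat] = True
    np.maximum.at(radius.ravel(), flat, rad[piece])
    return mask, radius


def _dropout_edges(raw, dropout, side, rng):
    """Random edge subset whose centerline-pixel union is ~(1-d) x the full one.

    Edges are admitted in random order while tracking the union of their
    rasterized pixels; admission stops once (1-d) of the full union is
    covered (overshoot at most one edge).
    """
    if not raw or dropout <= 0:
        return list(raw)
    p0 = np.asarray([e[0] for e in raw], dtype=float)
    p1 = np.asarray([e[1] for e in raw], dtype=float)
    lengths = np.hypot(*(p1 - p0).T)
    steps = np.maximum(np.ceil(lengths / 0.4).astype(int) + 1, 2)
    piece = np.repeat(np.arange(len(steps)), steps)
    j = np.arange(int(steps.sum())) - np.repeat(np.cumsum(steps) - steps, steps)
    t = (j / (steps[piece] - 1))[:, None]
    ij = np.clip(np.round(p0[piece] * (1 - t) + p1[piece] * t).astype(int), 0, side - 1)
    flat = ij[:, 0] * side + ij[:, 1]
    bounds = np.r_[0, np.cumsum(steps)]
    per_edge = [np.unique(flat[bounds[e]:bounds[e + 1]]) for e in range(len(raw))]
    full = len(np.unique(flat))
    target = (1.0 - dropout) * full
    seen = np.zeros(side * side, dtype=bool)
    kept_ids = []
    covered = 0
    for e in rng.permutation(len(raw)):
        px = per_edge[e]
        new = int((~seen[px]).sum())
        if covered + new > target:
            continue  # would overshoot; a shorter edge may still fit
        seen[px] = True
        covered += new
        kept_ids.append(e)
        if target - covered < 1:
            break
    return [raw[i] for i in sorted(kept_ids)]


# ---------------------------------------------------------------------------
# network generation


def generate_capillary_network(
    image_side: int = DEFAULT_IMAGE_SIDE,
    preset: GroupPreset = DEFAULT_PRESETS["control"],
    seed: int = 0,
    point_density: float = 0.0097,
    base_width: float = 2.7,
    faz_radius_frac: float = 0.095,
    n_trunks: int = 4,
    width_jitter: tuple = (0.92, 1.08),
) -> VesselNetworkTruth:
    """Generate a perturbed-Voronoi capillary mesh with a central FAZ.

    The mesh is the edge set of a Voronoi diagram over a jittered grid of
    seed points (density ``point_density`` points/px^2, which sets the
    undropped skeleton density), minus a ``dropout_fraction`` of edges removed
    uniformly at random (an exact count, for low between-image variance) and
    minus anything inside the FAZ disk.  A few wider trunk vessels cross the
    field to give the caliber distribution a realistic tail.  All calibers are
    multiplied by ``dilation_factor``.

    Deterministic for a fixed ``(seed, preset, image_side)``.
    """
    if image_side < 64:
        raise ValueError("image_side must be at least 64 px")
    rng = substream(seed, "network")
    side = int(image_side)
    center = np.array([side / 2.0, side / 2.0])
    faz_radius = faz_radius_frac * side

    # jittered-grid seed points -> Voronoi ridges
    spacing = 1.0 / math.sqrt(point_density)
    n_grid = int(math.ceil(side / spacing)) + 2
    gr, gc = np.meshgrid(np.arange(n_grid), np.arange(n_grid), indexing="ij")
    pts = np.stack([gr.ravel(), gc.ravel()], axis=1) * spacing - spacing / 2.0
    pts = pts + rng.uniform(-0.48 * spacing, 0.48 * spacing, size=pts.shape)

    from scipy.spatial import Voronoi

    vor = Voronoi(pts)
    margin = 1.0
    raw = []
    for v0, v1 in vor.ridge_vertices:
        if v0 < 0 or v1 < 0:
            continue
        clipped = _clip_to_box(vor.vertices[v0], vor.vertices[v1], margin, side - 1 - margin)
        if clipped is None:
            continue
        p0, p1 = clipped
        if float((p1 - p0) @ (p1 - p0)) < 1.0:
            continue
        raw.append((p0, p1))

    # dropout removes edges until the *rasterized centerline pixel count*
    # scales as (1 - d) x the undropped count: edges are admitted in random
    # order, tracking the union of their pixels, until the target is reached.
    # This keeps the skeleton-length scaling linear in d despite junction
    # pixel sharing, and has low between-image variance.
    kept = _dropout_edges(raw, preset.dropout_fraction, side, rng)

    segments, widths = [], []
    for p0, p1 in kept:
        for q0, q1 in _clip_outside_circle(p0, p1, center, faz_radius):
            w = base_width * preset.dilation_factor * rng.uniform(*width_jitter)
            segments.append([q0, q1])
            widths.append(w)

    # trunk vessels: gently curved chords crossing the field
    for _ in range(n_trunks):
        theta = rng.uniform(0, 2 * math.pi)
        offset = rng.uniform(0.18, 0.42) * side * rng.choice([-1.0, 1.0])
        direction = np.array([math.cos(theta), math.sin(theta)])
        normal = np.array([-direction[1], direction[0]])
        amp = rng.uniform(2.0, 7.0)
        phase = rng.uniform(0, 2 * math.pi)
        t = np.linspace(-0.75 * side, 0.75 * side, 40)
        pts_t = (
            center
            + offset * normal
            + t[:, None] * direction
            + (amp * np.sin(2 * math.pi * t / (0.9 * side) + phase))[:, None] * normal
        )
        w = base_width * preset.dilation_factor * rng.uniform(1.5, 1.9)
        for k in range(len(pts_t) - 1):
            clipped = _clip_to_box(pts_t[k], pts_t[k + 1], margin, side - 1 - margin)
            if clipped is None:
                continue
            for q0, q1 in _clip_outside_circle(clipped[0], clipped[1], center, faz_radius):
                segments.append([q0, q1])
                widths.append(w)

    mask, _ = _raster_centerlines(segments, widths, side)
    # FAZ invariant: no centerline pixel inside the disk (guard the raster too)
    rr, cc = np.nonzero(mask)
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 < faz_radius**2
    mask[rr[inside], cc[inside]] = False

    n_skel = int(mask.sum())
    if widths:
        lengths = np.array(
            [math.dist(seg[0], seg[1]) for seg in segments], dtype=float
        )
        mean_w = float(np.average(widths, weights=lengths))
    else:
        mean_w = 0.0

    return VesselNetworkTruth(
        segments=segments,
        widths=widths,
        faz_radius=faz_radius,
        image_side=side,
        true_skeleton_pixels=n_skel,
        true_mean_width=mean_w,
    )


def rasterize_angiogram(
    truth: VesselNetworkTruth,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
):
    """Render a truth network into an 8-bit angiogram plus ground-truth masks.

    Returns ``(AngiogramImage, vessel_mask, skeleton_mask)``.  The vessel mask
    contains every pixel whose center lies within half a caliber of the
    nearest centerline pixel; the skeleton mask is the rasterized centerline
    itself.  With ``speckle_sd = 0`` and ``background_level = 0`` the image is
    nonzero exactly on the vessel mask.
    """
    noise = noise or NoiseModel()
    side = truth.image_side
    centerline, _ = _raster_centerlines(truth.segments, truth.widths, side)
    # FAZ guard as in generate_capillary_network
    c = side / 2.0
    rr, cc = np.nonzero(centerline)
    inside = (rr - c) ** 2 + (cc - c) ** 2 < truth.faz_radius**2
    centerline[rr[inside], cc[inside]] = False

    # vessel mask rendered at 2x and area-downsampled, so effective caliber
    # responds smoothly to sub-pixel width changes
    scale = 2
    cl2, rad2 = _raster_centerlines(truth.segments, truth.widths, side, scale=scale)
    rr2, cc2 = np.nonzero(cl2)
    c2 = c * scale + (scale - 1) / 2.0
    inside2 = (rr2 - c2) ** 2 + (cc2 - c2) ** 2 < (truth.faz_radius * scale) ** 2
    cl2[rr2[inside2], cc2[inside2]] = False
    if cl2.any():
        dist2, (ir2, ic2) = ndimage.distance_transform_edt(~cl2, return_indices=True)
        mask2 = dist2 <= rad2[ir2, ic2]
        mask = mask2.reshape(side, scale, side, scale).mean(axis=(1, 3)) >= 0.5
    else:
        mask = np.zeros((side, side), dtype=bool)

    rng = substream(seed, "raster")
    img = np.full((side, side), noise.background_level, dtype=float)
    img[mask] = noise.vessel_level
    if noise.speckle_sd > 0:
        img += rng.normal(0.0, noise.speckle_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return (
        AngiogramImage(pixels=img),
        mask,
        centerline,
    )


# ---------------------------------------------------------------------------
# preset calibration


def _measure_preset(
    preset: GroupPreset,
    seeds,
    image_side: int,
    noise: NoiseModel,
    method: str,
):
    vsds, vdis = [], []
    for s in seeds:
        truth = generate_capillary_network(image_side, preset, seed=int(s))
        img, _, _ = rasterize_angiogram(truth, noise, seed=int(s))
        m = quantify(img, method=method)
        vsds.append(m.vsd)
        vdis.append(m.vdi if m.vdi is not None else np.nan)
    return np.asarray(vsds), np.asarray(vdis)


def calibrate_preset(
    preset: GroupPreset,
    n_calib: int = 40,
    seed: int = 0,
    image_side: int = DEFAULT_IMAGE_SIDE,
    noise: Optional[NoiseModel] = None,
    method: str = DEFAULT_BINARIZATION,
    dropout_bracket=(0.0, 0.55),
    dilation_bracket=(0.75, 1.45),
) -> GroupPreset:
    """Fit the dropout and dilation knobs so rendered images hit the targets.

    Two nested 1-D monotone root-finds with common random numbers (the same
    ``n_calib`` network seeds at every knob value, so the objective is a
    smooth deterministic function of the knob): dilation is solved for the
    VDI target at each candidate dropout, and dropout for the VSD target.

    Raises
    ------
    CalibrationError
        If a target lies outside the range achievable within the knob
        brackets (the bracket and endpoint values are named in the message).
    """
    if n_calib < 10:
        raise ValueError("n_calib must be at least 10")
    if preset.target_vsd_mean <= 0:
        raise CalibrationError(
            "target_vsd_mean must be positive: a nonempty network with an "
            "intact FAZ cannot reach VSD = 0"
        )
    noise = noise or NoiseModel()
    seeds = substream(seed, "calib", preset.name).integers(0, 2**31, size=n_calib)

    def mean_vdi_gap(dilation, dropout):
        p = replace(preset, dropout_fraction=dropout, dilation_factor=dilation)
        _, vdis = _measure_preset(p, seeds, image_side, noise, method)
        return float(np.nanmean(vdis)) - preset.target_vdi_mean

    def solve_dilation(dropout):
        lo, hi = dilation_bracket
        glo, ghi = mean_vdi_gap(lo, dropout), mean_vdi_gap(hi, dropout)
        if glo * ghi > 0:
            raise CalibrationError(
                f"VDI target {preset.target_vdi_mean} unreachable in dilation "
                f"bracket {dilation_bracket}: gaps ({glo:+.3f}, {ghi:+.3f})"
            )
        return optimize.brentq(
            mean_vdi_gap, lo, hi, args=(dropout,), xtol=5e-4, rtol=1e-4
        )

    def mean_vsd_gap(dropout, dilation):
        p = replace(preset, dropout_fraction=dropout, dilation_factor=dilation)
        vsds, _ = _measure_preset(p, seeds, image_side, noise, method)
        return float(np.mean(vsds)) - preset.target_vsd_mean

    # dropout moves VSD strongly and VDI only weakly; two passes converge
    dilation = 1.0
    dropout = preset.dropout_fraction
    for _ in range(2):
        lo, hi = dropout_bracket
        glo, ghi = mean_vsd_gap(lo, dilation), mean_vsd_gap(hi, dilation)
        if glo * ghi > 0:
            raise CalibrationError(
                f"VSD target {preset.target_vsd_mean} unreachable in dropout "
                f"bracket {dropout_bracket}: gaps ({glo:+.4f}, {ghi:+.4f})"
            )
        dropout = optimize.brentq(
            mean_vsd_gap, lo, hi, args=(dilation,), xtol=1e-3, rtol=1e-3
        )
        dilation = solve_dilation(dropout)
    return replace(preset, dropout_fraction=float(dropout), dilation_factor=float(dilation))


def evaluate_calibrated_preset(
    preset: GroupPreset,
    n_images: int = 100,
    seed: int = 0,
    n_calib: int = 40,
    image_side: int = DEFAULT_IMAGE_SIDE,
    noise: Optional[NoiseModel] = None,
    method: str = DEFAULT_BINARIZATION,
) -> dict:
    """Calibrate a group preset, then measure fresh images with the metrics
    pipeline.

    Returns the calibrated preset plus the mean/SD of measured VSD and VDI
    over ``n_images`` angiograms generated from seeds independent of the
    calibration seeds.
    """
    noise = noise or NoiseModel()
    fitted = calibrate_preset(
        preset, n_calib=n_calib, seed=seed, image_side=image_side,
        noise=noise, method=method,
    )
    eval_seeds = substream(seed, "eval", preset.name).integers(0, 2**31, size=n_images)
    vsds, vdis = _measure_preset(fitted, eval_seeds, image_side, noise, method)
    return {
        "preset": fitted,
        "n_images": n_images,
        "mean_vsd": float(np.mean(vsds)),
        "sd_vsd": float(np.std(vsds, ddof=1)),
        "mean_vdi": float(np.nanmean(vdis)),
        "sd_vdi": float(np.nanstd(vdis, ddof=1)),
    }


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class GroupCounts:
    eyes: int
    subjects: int

    def __post_init__(self) -> None:
        if not (self.subjects <= self.eyes <= 2 * self.subjects):
            raise ValueError("need subjects <= eyes <= 2*subjects per group")


@dataclass
class CohortConfig:
    """Structure of one simulated cohort.

    ``prevalence`` maps group name to ``{female, htn, hld}`` probabilities;
    ``age`` maps group name to ``(mean, sd)`` in years.  ``within_subject_corr``
    is the correlation of the two eyes' metrics within a subject, induced by a
    shared subject-level component.  Center membership is uniform over
    ``center_count`` centers; centers shift both metrics by small Gaussian
    offsets (``center_sd_vsd``, ``center_sd_vdi``).
    """

    cohort_id: int
    counts: dict  # group -> GroupCounts
    prevalence: dict  # group -> {"female": p, "htn": p, "hld": p}
    age: dict  # group -> (mean, sd)
    presets: dict = field(default_factory=lambda: dict(DEFAULT_PRESETS))
    within_subject_corr: float = 0.5
    eye_discordance: float = 0.3
    center_count: int = 3
    center_sd_vsd: float = 0.0005
    center_sd_vdi: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_subject_corr <= 1.0):
            raise ValueError("within_subject_corr must be in [0, 1]")
        for g, pr in self.prevalence.items():
            for k, v in pr.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"prevalence {k} for group {g} outside [0, 1]")

    @classmethod
    def cohort1(cls, seed: int = 0, **kw) -> "CohortConfig":
        """Training-cohort structure: 509 eyes, 159/155/195 by group."""
        return cls(
            cohort_id=1,
            counts={
                "control": GroupCounts(159, 102),
                "mild": GroupCounts(155, 100),
                "referable": GroupCounts(195, 129),
            },
            prevalence={
                "control": {"female": 0.598, "htn": 0.176, "hld": 0.088},
                "mild": {"female": 0.420, "htn": 0.530, "hld": 0.370},
                "referable": {"female": 0.488, "htn": 0.705, "hld": 0.450},
            },
            age={
                "control": (51.0, 17.9),
                "mild": (57.3, 13.4),
                "referable": (57.3, 12.5),
            },
            seed=seed,
            **kw,
        )

    @classmethod
    def cohort2(cls, seed: int = 0, **kw) -> "CohortConfig":
        """Screening-clinic validation cohort: 85 eyes, mild/referable only."""
        kw.setdefault("presets", dict(COHORT2_PRESETS))
        kw.setdefault("center_count", 1)
        return cls(
            cohort_id=2,
            counts={
                "mild": GroupCounts(16, 12),
                "referable": GroupCounts(69, 42),
            },
            prevalence={
                "mild": {"female": 0.500, "htn": 0.583, "hld": 0.417},
                "referable": {"female": 0.405, "htn": 0.619, "hld": 0.429},
            },
            age={"mild": (50.5, 15.0), "referable": (54.0, 10.5)},
            seed=seed,
            **kw,
        )


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw an eye-level cohort table with the configured structure.

    VSD/VDI are Gaussian with the preset group means/SDs, decomposed into a
    subject-level component (variance fraction ``within_subject_corr``) plus
    an eye-level residual, so both eyes of a subject correlate at the
    configured level.  Binary covariates are subject-level Bernoulli draws at
    the group prevalences.  A fraction ``eye_discordance`` of two-eye
    subjects in adjacent severity classes exchange one eye's class label
    (count-preserving swaps), so DR severity is not perfectly concordant
    within subject and the subject random intercept stays identifiable.
    Deterministic per ``config.seed``.
    """
    rng = substream(config.seed, "cohort", config.cohort_id)
    rho = config.within_subject_corr
    center_fx_vsd = rng.normal(0.0, config.center_sd_vsd, size=config.center_count)
    center_fx_vdi = rng.normal(0.0, config.center_sd_vdi, size=config.center_count)

    rows = []
    sid = 0
    for group, counts in config.counts.items():
        preset = config.presets[group]
        prev = config.prevalence[group]
        age_mu, age_sd = config.age[group]
        n_two = counts.eyes - counts.subjects
        two_eye = np.zeros(counts.subjects, dtype=bool)
        two_eye[:n_two] = True
        rng.shuffle(two_eye)
        for j in range(counts.subjects):
            sid += 1
            center = int(rng.integers(config.center_count))
            female = int(rng.random() < prev["female"])
            htn = int(rng.random() < prev["htn"])
            hld = int(rng.random() < prev["hld"])
            age = float(np.clip(rng.normal(age_mu, age_sd), 18, 95))
            z_subj_vsd = rng.normal()
            z_subj_vdi = rng.normal()
            eyes = ["OD", "OS"] if two_eye[j] else [rng.choice(["OD", "OS"])]
            for eye in eyes:
                vsd = (
                    preset.target_vsd_mean
                    + center_fx_vsd[center]
                    + preset.target_vsd_sd
                    * (math.sqrt(rho) * z_subj_vsd + math.sqrt(1 - rho) * rng.normal())
                )
                vdi = (
                    preset.target_vdi_mean
                    + center_fx_vdi[center]
                    + preset.target_vdi_sd
                    * (math.sqrt(rho) * z_subj_vdi + math.sqrt(1 - rho) * rng.normal())
                )
                rows.append(
                    dict(
                        subject_id=f"C{config.cohort_id}S{sid:04d}",
                        eye=str(eye),
                        center_id=f"center{center + 1}",
                        cohort=config.cohort_id,
                        dr_class=group,
                        sex="F" if female else "M",
                        htn=htn,
                        hld=hld,
                        age=round(age, 1),
                        vsd=float(vsd),
                        vdi=float(vdi),
                        artifact_count=int(rng.poisson(2.0) % 10),
                        image_path="",
                    )
                )
    df = pd.DataFrame(rows)

    # count-preserving class swaps between adjacent severity groups: one eye
    # of a two-eye subject in class A trades labels with one eye of a two-eye
    # subject in class B, so some subjects carry eyes of differing severity
    groups = list(config.counts)
    eye_n = df.groupby("subject_id")["eye"].transform("size")
    used: set = set()
    for g_lo, g_hi in zip(groups[:-1], groups[1:]):
        cand_lo = np.array(
            [s for s in df.loc[(df.dr_class == g_lo) & (eye_n == 2), "subject_id"].unique()
             if s not in used]
        )
        cand_hi = np.array(
            [s for s in df.loc[(df.dr_class == g_hi) & (eye_n == 2), "subject_id"].unique()
             if s not in used]
        )
        n_swap = int(round(config.eye_discordance * min(len(cand_lo), len(cand_hi)) / 2))
        pick_lo = rng.choice(cand_lo, size=n_swap, replace=False)
        pick_hi = rng.choice(cand_hi, size=n_swap, replace=False)
        used.update(pick_lo)
        used.update(pick_hi)
        for s_lo, s_hi in zip(pick_lo, pick_hi):
            i_lo = df.index[df.subject_id == s_lo][1]
            i_hi = df.index[df.subject_id == s_hi][1]
            for i, new_class in ((i_lo, g_hi), (i_hi, g_lo)):
                p = config.presets[new_class]
                df.loc[i, ["dr_class", "vsd", "vdi"]] = (
                    new_class,
                    p.target_vsd_mean + p.target_vsd_sd * rng.normal(),
                    p.target_vdi_mean + p.target_vdi_sd * rng.normal(),
                )
    return df


def simulate_logistic_cohort(
    n_subjects: int = 330,
    beta: Optional[dict] = None,
    intercept: Optional[float] = None,
    subject_sd: float = 0.7,
    two_eye_prob: float = 0.55,
    vsd_mean: float = 0.142,
    vsd_sd: float = 0.013,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort with a *known* binary-outcome generating model, for validating
    the mixed-logit estimator (parameter recovery, CI coverage, calibration).

    The outcome is Bernoulli with logit = intercept + X beta + u_subject,
    u ~ N(0, subject_sd^2) shared by both eyes.  ``beta`` maps column names
    (vsd, female, htn, hld) to per-unit coefficients; e.g. an odds ratio of
    0.85 per +0.001 VSD is ``beta={"vsd": log(0.85)/0.001}``.
    """
    beta = dict(beta or {"vsd": math.log(0.85) / 0.001})
    if intercept is None:
        # center the linear predictor at zero for ~50% marginal prevalence
        means = {"vsd": vsd_mean, "female": 0.5, "htn": 0.45, "hld": 0.3}
        intercept = -sum(beta.get(k, 0.0) * m for k, m in means.items())
    rng = substream(seed, "logistic-cohort")
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0.0, subject_sd)
        female = int(rng.random() < 0.5)
        htn = int(rng.random() < 0.45)
        hld = int(rng.random() < 0.3)
        n_eyes = 2 if rng.random() < two_eye_prob else 1
        for eye in (["OD", "OS"] if n_eyes == 2 else ["OD"]):
            vsd = rng.normal(vsd_mean, vsd_sd)
            x = {"vsd": vsd, "female": female, "htn": htn, "hld": hld}
            eta = intercept + u + sum(beta.get(k, 0.0) * v for k, v in x.items())
            y = int(rng.random() < 1.0 / (1.0 + math.exp(-eta)))
            rows.append(
                dict(
                    subject_id=f"S{i:05d}",
                    eye=eye,
                    y=y,
                    vsd=vsd,
                    female=female,
                    htn=htn,
                    hld=hld,
                )
            )
    return pd.DataFrame(rows)


def save_angiogram(path, img: AngiogramImage, truth: Optional[VesselNetworkTruth] = None):
    """Write an angiogram as 8-bit PNG with a JSON ground-truth sidecar."""
    import imageio.v3 as iio

    path = str(path)
    iio.imwrite(path, img.pixels)
    if truth is not None:
        side = {
            "faz_radius": truth.faz_radius,
            "image_side": truth.image_side,
            "true_skeleton_pixels": truth.true_skeleton_pixels,
            "true_mean_width": truth.true_mean_width,
            "n_segments": len(truth.segments),
        }
        with open(path + ".json", "w") as fh:
            json.dump(side, fh, indent=1)
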