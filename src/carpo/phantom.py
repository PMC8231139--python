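"""Synthetic articulated-wrist phantom.

Generates 2D+time grayscale sequences of an eight-bone wrist performing
continuous radial-to-ulnar abduction ("waving"), together with
pixel-perfect ground-truth label masks and per-frame truth values for the
scapholunate (SL) gap, the lunotriquetral (LT) gap, and the wrist angle.
Every downstream stage (preprocessing, segmentation, post-processing,
metric extraction) can therefore be tested end-to-end without MRI data.

Geometry
--------
Bones are convex superellipse-like polygons laid out in a coronal plane at
realistic wrist proportions for a 168 mm field of view and scaled linearly
with the requested field of view.  The distal radius and ulna are fixed
(emulating the tourniquet fixation of the forearm in the movement device);
the six carpal bones rotate rigidly about a pivot on the forearm axis.
The proximal-row bones (scaphoid, lunate, triquetrum) are placed on a
common row line with cortex-to-cortex separations equal to the requested
SL/LT gap truth at the current pose, so the rasterized inter-bone
separations match the analytic truth to within one pixel.

Sign convention: radial deviation is negative, ulnar deviation positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import shapely
from shapely.geometry import Polygon
from scipy.ndimage import gaussian_filter

from .core import ImageSequence

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "healthy_sl_gap",
    "healthy_lt_gap",
    "injury_sl_gap",
    "injury_lt_gap",
    "wrist_pose_at",
    "gap_truth",
    "generate_sequence",
    "frame_acquisition_ms",
]

# Reference field of view (mm) at which the bone layout below is defined.
_REF_FOV_MM = 168.0

# Per-frame acquisition defaults of the emulated radial FLASH sequence.
DEFAULT_N_SPOKES = 21
DEFAULT_TR_MS = 4.5


def frame_acquisition_ms(n_spokes: int = DEFAULT_N_SPOKES, tr_ms: float = DEFAULT_TR_MS) -> int:
    """Per-frame acquisition time in ms: spokes x repetition time, rounded half-up.

    With the default 21 radial spokes at TR = 4.5 ms this gives the 95 ms
    temporal resolution of the emulated acquisition.
    """
    return int(math.floor(n_spokes * tr_ms + 0.5))


# ---------------------------------------------------------------------------
# Gap-width truth models
# ---------------------------------------------------------------------------

#: Healthy SL gap at neutral (mm) and its linear trend with wrist angle
#: (mm per degree; slightly negative: the gap narrows in ulnar abduction).
HEALTHY_SL_MM = 1.7
HEALTHY_LT_MM = 1.3
HEALTHY_SLOPE_MM_PER_DEG = -0.002

#: Injured-wrist (SL ligament tear) piecewise-linear model: the SL gap is
#: pathologically widened (~4 mm) from the radial extreme up to +10 deg of
#: ulnar abduction, then closes toward ~1 mm at deep ulnar abduction, while
#: the LT gap starts low (~0.7 mm) and rises above 1 mm.
INJURY_SL_PLATEAU_MM = 4.0
INJURY_SL_ULNAR_MM = 1.0
INJURY_LT_PLATEAU_MM = 0.7
INJURY_LT_ULNAR_MM = 1.2
INJURY_BREAK_DEG = 10.0
INJURY_ULNAR_END_DEG = 35.0


def healthy_sl_gap(angle_deg: float) -> float:
    return HEALTHY_SL_MM + HEALTHY_SLOPE_MM_PER_DEG * angle_deg


def healthy_lt_gap(angle_deg: float) -> float:
    return HEALTHY_LT_MM + HEALTHY_SLOPE_MM_PER_DEG * angle_deg


def _piecewise(angle_deg: float, plateau: float, end_value: float) -> float:
    if angle_deg <= INJURY_BREAK_DEG:
        return plateau
    frac = (angle_deg - INJURY_BREAK_DEG) / (INJURY_ULNAR_END_DEG - INJURY_BREAK_DEG)
    return plateau + (end_value - plateau) * min(frac, 1.0)


def injury_sl_gap(angle_deg: float) -> float:
    return _piecewise(angle_deg, INJURY_SL_PLATEAU_MM, INJURY_SL_ULNAR_MM)


def injury_lt_gap(angle_deg: float) -> float:
    return _piecewise(angle_deg, INJURY_LT_PLATEAU_MM, INJURY_LT_ULNAR_MM)


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic wrist acquisition.

    Defaults emulate a 30 s real-time acquisition at 100 ms per frame on a
    168 x 168 px grid with 1.0 mm/px, sweeping from 15 deg of radial
    abduction to 35 deg of ulnar abduction and back once.
    """

    duration_s: float = 30.0
    frame_interval_ms: float = 100.0
    native_size_px: int = 168
    pixel_spacing_mm: float = 1.0
    angle_min_deg: float = -15.0
    angle_max_deg: float = 35.0
    sl_gap_fn: Callable[[float], float] | None = None
    lt_gap_fn: Callable[[float], float] | None = None
    injury_mode: bool = False
    noise_sigma: float = 0.05
    bone_intensity: float = 0.8
    background_intensity: float = 0.2
    blur_sigma_px: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.angle_min_deg < 0.0 < self.angle_max_deg):
            raise ValueError("angle range must satisfy angle_min < 0 < angle_max")
        if self.frame_interval_ms <= 0 or self.duration_s <= 0:
            raise ValueError("duration and frame interval must be positive")
        if self.native_size_px < 32:
            raise ValueError("native size too small to hold the wrist layout")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.sl_gap_fn is None:
            self.sl_gap_fn = injury_sl_gap if self.injury_mode else healthy_sl_gap
        if self.lt_gap_fn is None:
            self.lt_gap_fn = injury_lt_gap if self.injury_mode else healthy_lt_gap
        for angle in np.linspace(self.angle_min_deg, self.angle_max_deg, 101):
            if self.sl_gap_fn(angle) <= 0 or self.lt_gap_fn(angle) <= 0:
                raise ValueError("gap functions must be strictly positive over the motion range")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * 1000.0 / self.frame_interval_ms))

    @property
    def fov_mm(self) -> float:
        return self.native_size_px * self.pixel_spacing_mm


@dataclass
class GroundTruth:
    """Per-frame truth channel emitted alongside the synthetic images."""

    times_ms: np.ndarray
    angle_deg: np.ndarray
    sl_gap_mm: np.ndarray
    lt_gap_mm: np.ndarray
    masks: np.ndarray  # (n, H, W) uint8 label maps
    pixel_spacing_mm: float = 1.0

    def __len__(self) -> int:
        return len(self.angle_deg)


# ---------------------------------------------------------------------------
# Motion profile
# ---------------------------------------------------------------------------


def wrist_pose_at(t: float, spec: PhantomSpec) -> float:
    """Wrist angle (deg) at time ``t`` seconds under a cosine-eased sweep.

    The wrist moves smoothly from the radial extreme at ``t = 0`` to the
    ulnar extreme at mid-sequence and back, completing one full abduction
    cycle over the acquisition:

        angle(t) = a_min + (a_max - a_min) * (1 - cos(2 pi t / T)) / 2
    """
    if not 0.0 <= t <= spec.duration_s:
        raise ValueError(f"t={t} outside the acquisition window [0, {spec.duration_s}] s")
    phase = 2.0 * math.pi * t / spec.duration_s
    ease = 0.5 * (1.0 - math.cos(phase))
    return spec.angle_min_deg + (spec.angle_max_deg - spec.angle_min_deg) * ease


def gap_truth(angle_deg: float, spec: PhantomSpec) -> tuple[float, float]:
    """True (SL, LT) gap widths in mm at the given wrist angle."""
    return float(spec.sl_gap_fn(angle_deg)), float(spec.lt_gap_fn(angle_deg))


# ---------------------------------------------------------------------------
# Bone geometry
# ---------------------------------------------------------------------------


def _superellipse(cx: float, cy: float, a: float, b: float, power: float = 2.5,
                  n_vertices: int = 72) -> Polygon:
    """Convex superellipse polygon |x/a|^p + |y/b|^p = 1 centered at (cx, cy)."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    ct, st = np.cos(t), np.sin(t)
    x = cx + a * np.sign(ct) * np.abs(ct) ** (2.0 / power)
    y = cy + b * np.sign(st) * np.abs(st) ** (2.0 / power)
    return Polygon(np.column_stack([x, y]))


# Reference layout (mm at 168 mm FOV).  The forearm axis is vertical with
# the hand pointing towards the top of the image; the ulna lies on the
# +x (ulnar) side.  The carpal pivot is the center of the forearm group's
# bounding box so the bounding-box wrist-angle convention recovers the pose.
_FOREARM_AXIS_X = 85.5
_PIVOT = np.array([85.5, 132.0])

_RADIUS_GEOM = dict(cx=74.0, cy=132.0, a=10.0, b=27.0, power=2.6)
_ULNA_GEOM = dict(cx=100.0, cy=132.0, a=7.0, b=27.0, power=2.6)

_PROX_ROW_Y = 88.0
_SCAPHOID_AB = (10.0, 9.0)
_LUNATE_AB = (7.0, 8.0)
_TRIQUETRUM_AB = (8.0, 7.0)

# trapezium+trapezoid and hamate are mirror images about the forearm axis
# so the distal-row bounding box is centered on the axis in neutral pose
_DISTAL_GEOMS = {
    8: dict(cx=64.5, cy=66.0, a=10.0, b=8.0, power=2.4),   # trapezium+trapezoid
    7: dict(cx=85.5, cy=64.0, a=9.0, b=10.0, power=2.4),   # capitate
    6: dict(cx=106.5, cy=66.0, a=10.0, b=8.0, power=2.4),  # hamate
}


def _rotate_about(poly: Polygon, pivot: np.ndarray, angle_deg: float) -> Polygon:
    """Rotate polygon about pivot; positive angles tilt the hand ulnarly.

    In image coordinates (y down) the matrix [[c,-s],[s,c]] moves points
    above the pivot towards +x for positive angles, matching the
    radial-negative / ulnar-positive convention with the ulna on +x.
    """
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    xy = np.asarray(poly.exterior.coords)[:-1] - pivot
    rot = xy @ np.array([[c, s], [-s, c]])  # row-vector form of [[c,-s],[s,c]]
    return Polygon(rot + pivot)


def _bone_polygons(angle_deg: float, sl_mm: float, lt_mm: float,
                   scale: float) -> dict[int, Polygon]:
    """All eight bone polygons (mm coordinates) at the given pose.

    ``scale`` maps the 168 mm reference layout onto the requested field of
    view.  Bone sizes and positions scale linearly; the SL/LT separations
    are absolute mm so the gap truth is respected at any field of view.
    """
    bones: dict[int, Polygon] = {}
    for cls, g in ((1, _RADIUS_GEOM), (2, _ULNA_GEOM)):
        bones[cls] = _superellipse(g["cx"] * scale, g["cy"] * scale,
                                   g["a"] * scale, g["b"] * scale, g["power"])

    # Proximal row on a straight row line: lunate centered on the forearm
    # axis, scaphoid radial of it, triquetrum ulnar, with cortex-to-cortex
    # separations equal to the requested gaps.
    a_s, b_s = (_SCAPHOID_AB[0] * scale, _SCAPHOID_AB[1] * scale)
    a_l, b_l = (_LUNATE_AB[0] * scale, _LUNATE_AB[1] * scale)
    a_t, b_t = (_TRIQUETRUM_AB[0] * scale, _TRIQUETRUM_AB[1] * scale)
    y_row = _PROX_ROW_Y * scale
    x_lun = _FOREARM_AXIS_X * scale
    x_sca = x_lun - a_l - sl_mm - a_s
    x_tri = x_lun + a_l + lt_mm + a_t
    prox = {
        3: _superellipse(x_sca, y_row, a_s, b_s, 2.3),
        4: _superellipse(x_lun, y_row, a_l, b_l, 2.3),
        5: _superellipse(x_tri, y_row, a_t, b_t, 2.3),
    }

    distal = {
        cls: _superellipse(g["cx"] * scale, g["cy"] * scale,
                           g["a"] * scale, g["b"] * scale, g["power"])
        for cls, g in _DISTAL_GEOMS.items()
    }

    pivot = _PIVOT * scale
    for cls, poly in {**prox, **distal}.items():
        bones[cls] = _rotate_about(poly, pivot, angle_deg)
    return bones


def _rasterize_bones(bones: dict[int, Polygon], n_px: int, spacing_mm: float) -> np.ndarray:
    """Label map from polygons; pixel centers at ((c+0.5), (r+0.5)) * spacing."""
    coords = (np.arange(n_px) + 0.5) * spacing_mm
    xx, yy = np.meshgrid(coords, coords)
    mask = np.zeros((n_px, n_px), dtype=np.uint8)
    for cls in sorted(bones):  # higher class drawn last
        inside = shapely.contains_xy(bones[cls], xx.ravel(), yy.ravel()).reshape(n_px, n_px)
        mask[inside] = cls
    return mask


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------


def generate_sequence(spec: PhantomSpec, supersample: int = 1
                      ) -> tuple[ImageSequence, GroundTruth]:
    """Render the phantom acquisition described by ``spec``.

    Parameters
    ----------
    spec : PhantomSpec
    supersample : int
        Truth-mask (and image) resolution multiplier.  ``supersample=2``
        renders on a grid with half the pixel spacing, which is the
        resolution at which gap widths are measured downstream.

    Returns
    -------
    (ImageSequence, GroundTruth)
        Noisy intensity frames and the matching noise-free truth channel.
        Deterministic for a fixed ``spec.seed``.
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    n = spec.n_frames
    n_px = spec.native_size_px * supersample
    spacing = spec.pixel_spacing_mm / supersample
    scale = spec.fov_mm / _REF_FOV_MM

    times_ms = np.arange(n) * spec.frame_interval_ms
    angles = np.array([wrist_pose_at(t / 1000.0, spec) for t in times_ms])
    sl = np.array([gap_truth(a, spec)[0] for a in angles])
    lt = np.array([gap_truth(a, spec)[1] for a in angles])

    # Gaps narrower than one pixel of the requested rendering grid cannot be
    # represented; the injured-wrist LT gap (~0.7 mm) needs supersample >= 2
    # at the native 1.0 mm spacing.
    min_gap = min(sl.min(), lt.min())
    if min_gap < spacing:
        raise ValueError(
            f"degenerate geometry: minimum gap {min_gap:.3f} mm is below one "
            f"pixel at the requested resolution ({spacing} mm)")

    rng = np.random.default_rng(spec.seed)
    frames = np.empty((n, n_px, n_px), dtype=np.float32)
    masks = np.empty((n, n_px, n_px), dtype=np.uint8)
    for k in range(n):
        bones = _bone_polygons(angles[k], sl[k], lt[k], scale)
        m = _rasterize_bones(bones, n_px, spacing)
        masks[k] = m
        img = np.where(m > 0, spec.bone_intensity, spec.background_intensity).astype(np.float32)
        if spec.blur_sigma_px > 0:
            img = gaussian_filter(img, spec.blur_sigma_px * supersample)
        frames[k] = img
    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, frames.shape).astype(np.float32)

    seq = ImageSequence(frames, pixel_spacing_mm=spacing,
                        frame_interval_ms=spec.frame_interval_ms)
    truth = GroundTruth(times_ms=times_ms, angle_deg=angles, sl_gap_mm=sl,
                        lt_gap_mm=lt, masks=masks, pixel_spacing_mm=spacing)
    return seq, truth
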