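"""Algorithmic measurement of carpal configuration from label masks.

Per frame, three diagnostic measures are derived from the segmentation:

* **SL gap width** — the distance between the ulnar cortex of the
  scaphoid and the radial cortex of the lunate, measured where a
  centerline routed along the proximal carpal row crosses the two
  cortices.
* **LT gap width** — analogously between the ulnar cortex of the lunate
  and the radial cortex of the triquetrum.
* **Wrist angle** — the signed angle between the long axis of the
  forearm (minimum-area bounding box of radius + ulna) and the vector
  joining the centers of the forearm box and of the distal-carpal-row
  box (hamate + capitate + trapezium/trapezoid).  Radial deviation is
  negative, ulnar deviation positive; the sign is resolved from which
  side of the forearm axis the ulna lies on.

The centerline is obtained by fusing the scaphoid, lunate and triquetrum
masks (union + morphological closing that bridges the inter-bone gaps),
skeletonizing the fused region to its medial axis, pruning the skeleton
to its longest path, and fitting a smoothing spline, oriented from the
scaphoid (radial) end to the triquetrum (ulnar) end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, interpolate
from shapely.geometry import MultiPoint
from skimage.morphology import skeletonize

from .core import (DISTAL_ROW, FOREARM_CLASSES, LUNATE, SCAPHOID, TRIQUETRUM,
                   validate_label_mask)

__all__ = [
    "Centerline",
    "WristMetrics",
    "fuse_proximal_row",
    "carpal_centerline",
    "gap_widths",
    "wrist_angle",
    "quantify_sequence",
    "bin_by_angle",
]

#: Default closing radius (px) used to bridge the inter-bone gaps when
#: fusing the proximal row; 5 px bridges gaps up to ~5 mm at 0.5 mm/px.
DEFAULT_FUSE_RADIUS_PX = 5

#: Sampling step (in px) along the fitted centerline when locating
#: cortex crossings; sub-pixel crossings are linearly interpolated.
_ARC_STEP_PX = 0.05


@dataclass
class Centerline:
    """Ordered sub-pixel (x, y) points, oriented radial -> ulnar."""

    points: np.ndarray  # (n, 2) in pixel units

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("centerline needs an (n>=2, 2) point array")

    @property
    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class WristMetrics:
    """Per-frame metric series with validity flags (CSV-exportable)."""

    frame: np.ndarray
    time_ms: np.ndarray
    wrist_angle_deg: np.ndarray
    sl_gap_mm: np.ndarray
    lt_gap_mm: np.ndarray
    valid_sl: np.ndarray
    valid_lt: np.ndarray
    valid_angle: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frame, "time_ms": self.time_ms,
            "wrist_angle_deg": self.wrist_angle_deg,
            "sl_gap_mm": self.sl_gap_mm, "lt_gap_mm": self.lt_gap_mm,
            "valid_sl": self.valid_sl, "valid_lt": self.valid_lt,
            "valid_angle": self.valid_angle,
        })

    def __len__(self) -> int:
        return len(self.frame)


class FusionError(RuntimeError):
    """Raised when the proximal-row bones cannot be bridged into one region."""


# ---------------------------------------------------------------------------
# Proximal-row fusion and centerline
# ---------------------------------------------------------------------------


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    return x * x + y * y <= r * r


def fuse_proximal_row(mask: np.ndarray, closing_radius_px: int = DEFAULT_FUSE_RADIUS_PX,
                      max_radius_px: int = 4 * DEFAULT_FUSE_RADIUS_PX) -> np.ndarray:
    """Union of scaphoid, lunate and triquetrum, closed into one region.

    The closing radius grows (up to ``max_radius_px``) until the union is
    4-connected; a :class:`FusionError` is raised if the bones stay apart
    or fewer than two of them are present.
    """
    mask = validate_label_mask(mask)
    union = np.isin(mask, (SCAPHOID, LUNATE, TRIQUETRUM))
    n_present = sum(bool((mask == c).any()) for c in (SCAPHOID, LUNATE, TRIQUETRUM))
    if n_present < 2:
        raise FusionError("need at least two proximal-row bones to fuse")
    radius = int(closing_radius_px)
    while radius <= max_radius_px:
        fused = ndimage.binary_closing(union, structure=_disk(radius),
                                       iterations=1)
        _, nlab = ndimage.label(fused)
        if nlab == 1:
            return fused
        radius += 2
    raise FusionError(
        f"proximal-row bones too far apart to bridge (max radius {max_radius_px} px)")


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Longest geodesic path through a skeleton, by double BFS over the
    8-connected skeleton pixel graph."""
    pts = np.argwhere(skel)
    if len(pts) == 0:
        raise ValueError("empty skeleton")
    index = {tuple(p): i for i, p in enumerate(pts)}
    nbrs: list[list[int]] = [[] for _ in pts]
    for i, (r, c) in enumerate(pts):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    nbrs[i].append(j)

    def bfs(start: int):
        prev = np.full(len(pts), -1, dtype=int)
        dist = np.full(len(pts), -1, dtype=int)
        dist[start] = 0
        queue = [start]
        for u in queue:
            for v in nbrs[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    prev[v] = u
                    queue.append(v)
        far = int(np.argmax(dist))
        return far, prev

    a, _ = bfs(0)
    b, prev = bfs(a)
    path = [b]
    while prev[path[-1]] >= 0:
        path.append(int(prev[path[-1]]))
    return pts[path[::-1]]  # (n, 2) in (row, col)


def carpal_centerline(fused: np.ndarray, smooth: float | None = None,
                      spline_degree: int = 3) -> Centerline:
    """Centerline of the fused proximal row.

    Medial-axis skeleton -> longest path -> smoothing-spline fit,
    evaluated densely; sub-pixel (x, y) coordinates.  Orientation is the
    raw path order; use :func:`_orient_centerline` (done automatically in
    :func:`gap_widths`) or reorder externally for the radial->ulnar
    contract when bone masks are available.
    """
    fused = np.asarray(fused, dtype=bool)
    _, nlab = ndimage.label(fused)
    if nlab != 1:
        raise ValueError("fused region must be a single connected component")
    skel = skeletonize(fused)
    path = _longest_skeleton_path(skel)
    if len(path) < 4:
        raise ValueError("skeleton degenerates to a point")
    # trim diagonal end-spurs: skeleton branches running into corners lie
    # close to the boundary, where the distance transform is well below the
    # medial half-width
    dt = ndimage.distance_transform_edt(fused)
    depth = dt[path[:, 0], path[:, 1]]
    cutoff = 0.7 * np.median(depth)
    inside = np.flatnonzero(depth >= cutoff)
    if len(inside) >= 4:
        path = path[inside[0]:inside[-1] + 1]
    xy = path[:, ::-1].astype(float)  # (x, y)
    # arc-length parameterized smoothing spline
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    u /= u[-1]
    k = min(spline_degree, len(xy) - 1)
    s = smooth if smooth is not None else 2.0 * len(xy)
    tck, _ = interpolate.splprep([xy[:, 0], xy[:, 1]], u=u, s=s, k=k)
    n_eval = max(2 * len(xy), 64)
    uu = np.linspace(0.0, 1.0, n_eval)
    out = np.column_stack(interpolate.splev(uu, tck))
    return Centerline(out)


def _orient_centerline(cl: Centerline, mask: np.ndarray) -> Centerline:
    """Ensure the first point lies on the radial (scaphoid) side.

    Falls back to whichever two proximal-row bones are present, ordered
    radially (scaphoid -> lunate -> triquetrum).
    """
    present = [c for c in (SCAPHOID, LUNATE, TRIQUETRUM) if (mask == c).any()]
    if len(present) < 2:
        return cl
    sca_c = np.argwhere(mask == present[0]).mean(axis=0)[::-1]
    tri_c = np.argwhere(mask == present[-1]).mean(axis=0)[::-1]
    d_start = np.linalg.norm(cl.points[0] - sca_c) + np.linalg.norm(cl.points[-1] - tri_c)
    d_flip = np.linalg.norm(cl.points[-1] - sca_c) + np.linalg.norm(cl.points[0] - tri_c)
    if d_flip < d_start:
        return Centerline(cl.points[::-1].copy())
    return cl


# ---------------------------------------------------------------------------
# Gap widths
# ---------------------------------------------------------------------------


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1]
    ss = np.arange(0.0, total + step / 2, step)
    x = np.interp(ss, s, points[:, 0])
    y = np.interp(ss, s, points[:, 1])
    return np.column_stack([x, y])


def _extend_centerline(points: np.ndarray, pad_px: float) -> np.ndarray:
    """Extrapolate both ends tangentially so the curve fully traverses the
    flanking bones even when the skeleton stops inside them."""
    d0 = points[0] - points[1]
    d1 = points[-1] - points[-2]
    d0 /= max(np.linalg.norm(d0), 1e-9)
    d1 /= max(np.linalg.norm(d1), 1e-9)
    head = points[0] + np.outer(np.linspace(pad_px, 0, 32, endpoint=False), d0)
    tail = points[-1] + np.outer(np.linspace(0, pad_px, 33)[1:], d1)
    return np.vstack([head, points, tail])


def _crossing_gap(samples: np.ndarray, in_a: np.ndarray, in_b: np.ndarray,
                  step: float) -> float | None:
    """Distance between the last exit from region a and the first entry
    into region b after it, walking the sampled curve."""
    idx_a = np.flatnonzero(in_a)
    if len(idx_a) == 0:
        return None
    exit_a = idx_a[-1]
    idx_b = np.flatnonzero(in_b)
    idx_b = idx_b[idx_b > exit_a]
    if len(idx_b) == 0:
        return None
    entry_b = idx_b[0]
    # sub-pixel: the cortex lies between the last inside and first outside
    # samples; with a fine step the midpoint is within step/2 of the edge
    p_exit = 0.5 * (samples[exit_a] + samples[min(exit_a + 1, len(samples) - 1)])
    p_entry = 0.5 * (samples[entry_b] + samples[max(entry_b - 1, 0)])
    return float(np.linalg.norm(p_entry - p_exit))


def gap_widths(centerline: Centerline, mask: np.ndarray, spacing_mm: float
               ) -> tuple[float | None, float | None]:
    """SL and LT gap widths (mm) measured along the centerline.

    The centerline is oriented radial->ulnar, extended tangentially, and
    sampled finely; the SL gap is the Euclidean distance between the
    point where the curve leaves the scaphoid and the point where it
    enters the lunate (LT analogously lunate -> triquetrum).  ``None`` is
    returned for a gap whose flanking bones the curve fails to traverse.
    """
    mask = validate_label_mask(mask)
    cl = _orient_centerline(centerline, mask)
    pts = _extend_centerline(cl.points, pad_px=max(8.0, 2.0 / spacing_mm))
    samples = _resample_polyline(pts, _ARC_STEP_PX)
    h, w = mask.shape
    cols = np.clip(np.round(samples[:, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.round(samples[:, 1]).astype(int), 0, h - 1)
    labels = mask[rows, cols]

    def seg_gap(c_from: int, c_to: int) -> float | None:
        in_a = labels == c_from
        in_b = labels == c_to
        d = _crossing_gap(samples, in_a, in_b, _ARC_STEP_PX)
        return None if d is None else d * spacing_mm

    return seg_gap(SCAPHOID, LUNATE), seg_gap(LUNATE, TRIQUETRUM)


# ---------------------------------------------------------------------------
# Wrist angle
# ---------------------------------------------------------------------------


def _min_area_rect(binary: np.ndarray):
    """(center_xy, long_axis_unit_xy) of the minimum-area rotated rectangle
    around the True pixels (shapely minimum_rotated_rectangle on the pixel
    corner cloud)."""
    pts = np.argwhere(binary)
    if len(pts) == 0:
        return None
    # pixel corners, so single-row groups still span a rectangle
    corners = np.concatenate([pts + d for d in
                              ([-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5])])
    hull = MultiPoint(corners[:, ::-1]).convex_hull  # (x, y)
    rect = hull.minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords)[:4]
    center = xy.mean(axis=0)
    e1 = xy[1] - xy[0]
    e2 = xy[2] - xy[1]
    long_edge = e1 if np.linalg.norm(e1) >= np.linalg.norm(e2) else e2
    axis = long_edge / max(np.linalg.norm(long_edge), 1e-9)
    return center, axis


def wrist_angle(mask: np.ndarray) -> float | None:
    """Signed wrist angle (deg): radial negative, ulnar positive.

    Minimum-area bounding boxes are fitted to the forearm group
    (radius + ulna) and to the distal carpal row; the angle is measured
    between the forearm box long axis (directed towards the carpus) and
    the vector joining the two box centers.  The ulnar side is identified
    from the radius->ulna centroid direction.  Returns ``None`` when a
    group is missing.
    """
    mask = validate_label_mask(mask)
    forearm = np.isin(mask, FOREARM_CLASSES)
    distal = np.isin(mask, DISTAL_ROW)
    radius = np.argwhere(mask == FOREARM_CLASSES[0])
    ulna = np.argwhere(mask == FOREARM_CLASSES[1])
    if not forearm.any() or not distal.any() or len(radius) == 0 or len(ulna) == 0:
        return None
    fa = _min_area_rect(forearm)
    da = _min_area_rect(distal)
    f_center, f_axis = fa
    d_center, _ = da
    v = d_center - f_center
    if np.dot(f_axis, v) < 0:
        f_axis = -f_axis  # direct the forearm axis towards the carpus
    vn = np.linalg.norm(v)
    if vn < 1e-9:
        return 0.0
    v = v / vn
    cos_a = float(np.clip(np.dot(f_axis, v), -1.0, 1.0))
    angle = np.degrees(np.arccos(cos_a))
    # sign: positive when the carpal center deviates towards the ulnar side
    ulnar_dir = ulna.mean(axis=0)[::-1] - radius.mean(axis=0)[::-1]
    perp = ulnar_dir - np.dot(ulnar_dir, f_axis) * f_axis
    if np.linalg.norm(perp) > 1e-9:
        sign = np.sign(np.dot(v - np.dot(v, f_axis) * f_axis, perp))
        if sign != 0:
            angle *= sign
    return float(angle)


# ---------------------------------------------------------------------------
# Sequence-level quantification
# ---------------------------------------------------------------------------


def quantify_sequence(masks: np.ndarray, spacing_mm: float,
                      frame_interval_ms: float = 100.0,
                      fuse_radius_px: int = DEFAULT_FUSE_RADIUS_PX) -> WristMetrics:
    """Per-frame SL/LT gap widths and wrist angle for a mask sequence.

    Frames where a measurement fails are flagged invalid (NaN value), not
    dropped, so the output always has one row per frame.
    """
    masks = np.asarray(masks)
    if masks.ndim != 3:
        raise ValueError("need an (n, H, W) mask sequence")
    n = masks.shape[0]
    sl = np.full(n, np.nan)
    lt = np.full(n, np.nan)
    ang = np.full(n, np.nan)
    for k in range(n):
        m = masks[k]
        a = wrist_angle(m)
        if a is not None:
            ang[k] = a
        try:
            fused = fuse_proximal_row(m, closing_radius_px=fuse_radius_px)
            cl = carpal_centerline(fused)
            g_sl, g_lt = gap_widths(cl, m, spacing_mm)
        except (FusionError, ValueError):
            g_sl = g_lt = None
        if g_sl is not None:
            sl[k] = g_sl
        if g_lt is not None:
            lt[k] = g_lt
    return WristMetrics(
        frame=np.arange(n), time_ms=np.arange(n) * float(frame_interval_ms),
        wrist_angle_deg=ang, sl_gap_mm=sl, lt_gap_mm=lt,
        valid_sl=np.isfinite(sl), valid_lt=np.isfinite(lt),
        valid_angle=np.isfinite(ang))


def bin_by_angle(metrics: WristMetrics | pd.DataFrame, bin_deg: float = 5.0
                 ) -> pd.DataFrame:
    """Mean +/- SD of the SL/LT gaps grouped into wrist-angle bins.

    Bins are ``bin_deg``-wide half-open intervals aligned to multiples of
    the bin width, covering the observed range of motion; empty bins are
    omitted.
    """
    df = metrics.to_dataframe() if isinstance(metrics, WristMetrics) else metrics
    df = df[df["valid_angle"]]
    if len(df) == 0:
        raise ValueError("no valid frames to bin")
    lo = np.floor(df["wrist_angle_deg"].min() / bin_deg) * bin_deg
    hi = np.ceil(df["wrist_angle_deg"].max() / bin_deg) * bin_deg
    if hi == lo:
        hi = lo + bin_deg
    edges = np.arange(lo, hi + bin_deg / 2, bin_deg)
    df = df.copy()
    df["angle_bin"] = pd.cut(df["wrist_angle_deg"], edges, include_lowest=True)
    rows = []
    for interval, grp in df.groupby("angle_bin", observed=True):
        rows.append({
            "bin_left_deg": interval.left, "bin_right_deg": interval.right,
            "bin_center_deg": interval.mid, "n": len(grp),
            "sl_mean_mm": grp["sl_gap_mm"].mean(), "sl_sd_mm": grp["sl_gap_mm"].std(ddof=0),
            "lt_mean_mm": grp["lt_gap_mm"].mean(), "lt_sd_mm": grp["lt_gap_mm"].std(ddof=0),
        })
    return pd.DataFrame(rows).sort_values("bin_center_deg").reset_index(drop=True)
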