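"""Low-level 3D geometry shared by the simulator and the probes.

Coordinates are (x, y, z) in micrometres with y the "vertical" axis of the
vertical designs (rotations happen about y) and z the optical axis.
Counting rules use half-open boxes [lo, hi); clipping for length
measurement treats boxes as closed, which differs only on a null set.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "polyline_length",
    "rotation_about_y",
    "project_about_y",
    "clip_polyline_to_box",
    "clip_curves_to_box",
    "curves_total_length",
    "orthonormal_frame",
    "random_unit_vector",
]


def polyline_length(points: np.ndarray) -> float:
    """Exact Euclidean length of a polyline (sum over vertex-to-vertex steps)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def rotation_about_y(angle_deg: float) -> np.ndarray:
    """Rotation matrix about the vertical (y) axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def project_about_y(points: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about y by ``angle_deg`` and project along z.

    Returns the (x', y) coordinates of the vertical projection; y-parallel
    structures keep their length at every angle.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rot = pts @ rotation_about_y(angle_deg).T
    return rot[:, :2]


def _clip_segment_times(p: np.ndarray, q: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Liang-Barsky parametric clip of segment p->q against [lo, hi]."""
    d = q - p
    t0, t1 = 0.0, 1.0
    for ax in range(len(p)):
        if d[ax] == 0.0:
            if p[ax] < lo[ax] or p[ax] > hi[ax]:
                return None
        else:
            ta = (lo[ax] - p[ax]) / d[ax]
            tb = (hi[ax] - p[ax]) / d[ax]
            if ta > tb:
                ta, tb = tb, ta
            t0 = max(t0, ta)
            t1 = min(t1, tb)
            if t0 >= t1:
                return None
    return t0, t1


def clip_polyline_to_box(points, lo, hi, radii=None):
    """Clip a polyline to an axis-aligned box.

    Returns a list of ``(points, radii)`` runs (radii is None when not
    supplied); contiguous in-box stretches are merged into single runs so
    that distinct re-entries stay distinct polylines.  Total clipped length
    is conserved under any partition of the box into slabs.
    """
    pts = np.asarray(points, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    rad = None if radii is None else np.asarray(radii, dtype=float)

    runs = []
    cur_pts: list = []
    cur_rad: list = []
    prev_t1 = None

    def flush():
        nonlocal cur_pts, cur_rad
        if len(cur_pts) >= 2:
            runs.append(
                (np.asarray(cur_pts), np.asarray(cur_rad) if rad is not None else None)
            )
        cur_pts, cur_rad = [], []

    for i in range(len(pts) - 1):
        res = _clip_segment_times(pts[i], pts[i + 1], lo, hi)
        if res is None:
            flush()
            prev_t1 = None
            continue
        t0, t1 = res
        a = pts[i] + t0 * (pts[i + 1] - pts[i])
        b = pts[i] + t1 * (pts[i + 1] - pts[i])
        if rad is not None:
            ra = rad[i] + t0 * (rad[i + 1] - rad[i])
            rb = rad[i] + t1 * (rad[i + 1] - rad[i])
        if cur_pts and prev_t1 == 1.0 and t0 == 0.0:
            cur_pts.append(b)
            if rad is not None:
                cur_rad.append(rb)
        else:
            flush()
            cur_pts = [a, b]
            if rad is not None:
                cur_rad = [ra, rb]
        prev_t1 = t1
    flush()
    return runs


def clip_curves_to_box(curves, lo, hi):
    """Clip a list of ``(points, radii)`` curves to a box; see above."""
    out = []
    for pts, rad in curves:
        out.extend(clip_polyline_to_box(pts, lo, hi, rad))
    return out


def curves_total_length(curves) -> float:
    """Summed polyline length of ``(points, radii)`` curves."""
    return float(sum(polyline_length(pts) for pts, _ in curves))


def orthonormal_frame(direction: np.ndarray):
    """Two unit vectors completing ``direction`` to a right-handed frame."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def random_unit_vector(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Uniform direction(s) on the full sphere."""
    size = (3,) if n is None else (n, 3)
    v = rng.normal(size=size)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)
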