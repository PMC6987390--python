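"""Curve length from total vertical projections with cycloid test systems.

A 3D curve bounded in a thin slab is projected onto planes parallel to a
fixed "vertical" (y) axis at n evenly spaced rotation angles about that
axis.  Crossings I_j between the projections and a cycloid test system —
minor axis perpendicular to the vertical axis, the orientation required
for length (as opposed to surface) estimation — give

    L = 2 * (a/l) * (1/M) * mean_j(I_j)

with ``a/l`` the grid constant (test-system area per unit cycloid arc
length) and ``M`` the linear magnification (1 when coordinates are already
in um).  Dividing by a point-counted reference volume yields the length
density L_V.

Two counting modes exist: geometric (exact polyline/cycloid crossings,
via shapely) and image (crossing events between the cycloid path and a
skeletonized projection, where overlap masking can lose hits — a bias the
geometric mode quantifies).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, MultiLineString

from .errors import EstimateError, ParameterError

__all__ = [
    "TVPConfig",
    "TVPResult",
    "CycloidGrid",
    "PointGrid",
    "make_cycloid_grid",
    "cycloid_half_arch_length",
    "count_cycloid_intersections_geometric",
    "count_cycloid_intersections_image",
    "estimate_length_tvp",
    "point_count_volume",
    "estimate_lv_tvp",
]

DEFAULT_ANGLES = (0.0, 36.0, 72.0, 108.0, 144.0)


@dataclass(frozen=True)
class TVPConfig:
    """Vertical-projection protocol parameters.

    ``a_over_l`` is the grid constant in um^2 per um of cycloid arc;
    ``angles`` the projection angles (evenly spaced in [0, 180)); ``depth``
    the sub-stack depth in um (4 by default — shallow slabs limit overlap
    masking); ``magnification`` the linear magnification M (1 for
    physical-unit coordinates).
    """

    a_over_l: float = 25.0
    angles: tuple[float, ...] = DEFAULT_ANGLES
    depth: float = 4.0
    magnification: float = 1.0
    point_spacing: float = 20.0

    def __post_init__(self):
        if self.a_over_l <= 0:
            raise ParameterError("grid constant a/l must be positive")
        if len(self.angles) < 1:
            raise ParameterError("at least one projection angle is required")
        diffs = np.diff(np.asarray(self.angles, dtype=float))
        if len(diffs) and not np.allclose(diffs, diffs[0]):
            raise ParameterError("projection angles must be evenly spaced")

    @property
    def n(self) -> int:
        return len(self.angles)


@dataclass
class TVPResult:
    i_j: np.ndarray  # per-angle intersection counts
    l_hat_um: float
    v_ref_um3: float | None = None
    lv_um2: float | None = None


@dataclass
class CycloidGrid:
    """Tiling of cycloid arcs with constant grid constant a/l.

    Columns of arcs run along the vertical (y) axis (minor axis of each
    arc along x, i.e. perpendicular to vertical), spaced ``spacing`` apart
    in x; successive periods mirror their bulge so the system is symmetric.
    ``a/l = pi * spacing / 4`` independent of the rolling-circle radius.
    """

    r: float
    spacing: float
    phase: tuple[float, float]
    window: tuple[float, float, float, float]  # (x0, x1, y0, y1)
    orientation: str = "vertical"
    chord_max: float = 0.25
    arcs: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def a_over_l(self) -> float:
        return np.pi * self.spacing / 4.0

    def total_arc_length(self) -> float:
        return float(
            sum(np.linalg.norm(np.diff(a, axis=0), axis=1).sum() for a in self.arcs)
        )

    def as_multilinestring(self) -> MultiLineString:
        return MultiLineString([a.tolist() for a in self.arcs])


@dataclass
class PointGrid:
    """Square point grid for area estimation: area per point = spacing^2."""

    spacing: float
    offset: tuple[float, float]

    @property
    def area_per_point(self) -> float:
        return self.spacing**2


def cycloid_half_arch_length(r: float) -> float:
    """Arc length of one cycloid half-arch of rolling radius r (= 4 r)."""
    return 4.0 * r


def _cycloid_period(r: float, n_chords: int, mirror: bool) -> np.ndarray:
    """One full cycloid period as chords: advances 2*pi*r along y."""
    t = np.linspace(0.0, 2.0 * np.pi, n_chords + 1)
    x = r * (1.0 - np.cos(t))
    if mirror:
        x = -x
    y = r * (t - np.sin(t))
    return np.column_stack([x, y])


def make_cycloid_grid(
    a_over_l: float,
    window,
    rng: np.random.Generator,
    r: float | None = None,
    chord_max: float = 0.25,
    orientation: str = "vertical",
) -> CycloidGrid:
    """Cycloid test system over ``window`` = (x0, x1, y0, y1).

    The phase is uniformly random over one tile; arcs are subdivided into
    chords no longer than ``chord_max``.  ``orientation="rotated90"``
    builds the (incorrect for vertical designs) 90-degree-rotated system,
    kept for orientation-convention stress tests.
    """
    if a_over_l <= 0:
        raise ParameterError("grid constant a/l must be positive")
    if orientation not in ("vertical", "rotated90"):
        raise ParameterError("orientation must be 'vertical' or 'rotated90'")
    x0, x1, y0, y1 = map(float, window)
    if orientation == "rotated90":
        # build the standard system in swapped coordinates, then swap back:
        # a correctly tiled grid with the (wrong) 90-degree orientation
        x0, x1, y0, y1 = y0, y1, x0, x1
    spacing = 4.0 * a_over_l / np.pi
    if r is None:
        r = spacing / 4.0
    period = 2.0 * np.pi * r
    n_chords = max(16, int(np.ceil(8.0 * r / chord_max)))
    dx = float(rng.uniform(0.0, spacing))
    dy = float(rng.uniform(0.0, period))

    arcs: list[np.ndarray] = []
    # enlarge the covered range so bulges (width 2r) and phase are covered
    i_lo = int(np.floor((x0 - dx - 2.0 * r) / spacing))
    i_hi = int(np.ceil((x1 - dx + 2.0 * r) / spacing))
    j_lo = int(np.floor((y0 - dy - period) / period))
    j_hi = int(np.ceil((y1 - dy) / period))
    base = _cycloid_period(r, n_chords, mirror=False)
    base_m = _cycloid_period(r, n_chords, mirror=True)
    for i in range(i_lo, i_hi + 1):
        cx = dx + i * spacing
        for j in range(j_lo, j_hi + 1):
            cy = dy + j * period
            src = base if (j % 2 == 0) else base_m
            arc = src + np.array([cx, cy])
            # keep arcs overlapping the window
            if (
                arc[:, 0].max() < x0
                or arc[:, 0].min() > x1
                or arc[:, 1].max() < y0
                or arc[:, 1].min() > y1
            ):
                continue
            if orientation == "rotated90":
                arc = arc[:, ::-1]
            arcs.append(arc)
    return CycloidGrid(
        r=float(r),
        spacing=spacing,
        phase=(dx, dy),
        window=(x0, x1, y0, y1),
        orientation=orientation,
        chord_max=chord_max,
        arcs=arcs,
    )


def count_cycloid_intersections_geometric(polylines, grid: CycloidGrid) -> int:
    """Exact crossing count between 2D polylines and the cycloid system.

    Each polyline is intersected separately, so processes overlapping in
    projection but kept as distinct structures contribute separate hits.
    Collinear overlap (a null set for generic placements) counts once per
    contiguous stretch.
    """
    if not polylines:
        return 0
    grid_geom = grid.as_multilinestring()
    total = 0
    for pts in polylines:
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or len(pts) < 2:
            continue
        inter = grid_geom.intersection(LineString(pts))
        if inter.is_empty:
            continue
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            if g.geom_type == "Point":
                total += 1
            elif g.geom_type in ("LineString", "MultiPoint"):
                total += len(getattr(g, "geoms", [g]))
    return total


def count_cycloid_intersections_image(
    skeleton: np.ndarray,
    grid: CycloidGrid,
    pixel_size: float = 1.0,
    origin=(0.0, 0.0),
    dilate: int = 0,
) -> int:
    """Crossing events between the cycloid path and a skeleton image.

    The cycloid is sampled at sub-pixel steps; consecutive runs of
    skeleton hits along the path count as one event each (the image
    analogue of crossing a process's central spine).  Counting is
    deliberately conservative — grazing passes through diagonal pixel
    gaps may be missed, never double-counted — so image-mode counts can
    only fall below the exact geometric counts.  ``dilate`` optionally
    thickens the skeleton to trade that bias for near-miss false hits.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if skel.size == 0 or not skel.any():
        return 0
    if dilate > 0:
        from scipy.ndimage import binary_dilation

        skel = binary_dilation(skel, iterations=dilate)
    oy, ox = origin[1], origin[0]
    ny, nx = skel.shape
    total = 0
    step = 0.4 * pixel_size
    for arc in grid.arcs:
        seglen = np.linalg.norm(np.diff(arc, axis=0), axis=1)
        n_samples = max(2, int(np.ceil(seglen.sum() / step)))
        t = np.linspace(0.0, 1.0, n_samples)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        if cum[-1] == 0:
            continue
        s = t * cum[-1]
        xs = np.interp(s, cum, arc[:, 0])
        ys = np.interp(s, cum, arc[:, 1])
        col = np.floor((xs - ox) / pixel_size).astype(int)
        row = np.floor((ys - oy) / pixel_size).astype(int)
        inside = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)
        hits = np.zeros(n_samples, dtype=bool)
        hits[inside] = skel[row[inside], col[inside]]
        # one event per connected run of hits; runs separated by less than
        # ~1.5 px are merged so tangential pixel jitter is not re-counted
        gap_min = max(1, int(np.ceil(1.5 * pixel_size / step)))
        idx = np.flatnonzero(hits)
        if len(idx):
            total += 1 + int(np.count_nonzero(np.diff(idx) > gap_min))
    return total


def estimate_length_tvp(i_j, config: TVPConfig) -> float:
    """L = 2 (a/l) (1/M) mean_j(I_j), in um for calibrated coordinates."""
    i_j = np.asarray(i_j, dtype=float)
    if i_j.size < 1:
        raise ParameterError("need at least one projection count")
    return float(
        2.0 * config.a_over_l / config.magnification * i_j.mean()
    )


def point_count_volume(
    region_mask,
    spacing: float,
    depth: float,
    rng: np.random.Generator,
    window=None,
    pixel_size: float = 1.0,
) -> tuple[float, int]:
    """Reference volume by point counting on the 0-degree projection.

    ``region_mask`` is a 2D boolean tissue mask (pixel grid) or None for a
    full rectangular ``window`` = (x0, x1, y0, y1).  Returns (V_ref, hits)
    with V_ref = hits * spacing^2 * depth.
    """
    if spacing <= 0 or depth <= 0:
        raise ParameterError("spacing and depth must be positive")
    ox = float(rng.uniform(0.0, spacing))
    oy = float(rng.uniform(0.0, spacing))
    if region_mask is None:
        if window is None:
            raise ParameterError("window required when no mask is given")
        x0, x1, y0, y1 = map(float, window)
        xs = np.arange(x0 + ox, x1, spacing)
        ys = np.arange(y0 + oy, y1, spacing)
        hits = len(xs) * len(ys)
    else:
        mask = np.asarray(region_mask, dtype=bool)
        ny, nx = mask.shape
        xs = np.arange(ox, nx * pixel_size, spacing)
        ys = np.arange(oy, ny * pixel_size, spacing)
        gx, gy = np.meshgrid(xs, ys)
        col = np.floor(gx / pixel_size).astype(int)
        row = np.floor(gy / pixel_size).astype(int)
        ok = (col < nx) & (row < ny)
        hits = int(mask[row[ok], col[ok]].sum())
    return float(hits) * spacing**2 * depth, int(hits)


def estimate_lv_tvp(l_hat_um: float, v_ref_um3: float, volume_correction: float = 1.0) -> float:
    """Length density L_V = L / (V_ref * correction), in um^-2.

    ``volume_correction`` refers the measured (possibly z-collapsed)
    volume back to the cut-section volume, typically t_cut / t_bar_Q >= 1;
    1 means no shrinkage correction.
    """
    v = v_ref_um3 * volume_correction
    if v <= 0:
        raise EstimateError("zero reference volume: length density undefined")
    return l_hat_um / v
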