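"""Synthetic 3D microglial tissue with exact ground-truth morphometry.

The generator emulates two regimes of microglia in the superficial dorsal
horn of the mouse trigeminal system: a quiescent ("control") population of
sparse, finely ramified cells, and a reactive ("deafferented") population
at the peak of nerve-injury-induced microgliosis — five times denser, with
larger somata, roughly twice the primary processes, and arbors half as
long per cell.  Cells live in a rectangular tissue block; every quantity a
stereological estimator targets (total process length, cell count, soma
volumes) is available exactly from the model, so estimator bias can be
measured rather than assumed.

Somata are random-orientation ellipsoids with lognormal volumes.  Arbors
are recursive binary trees: primary counts follow a rounded Gamma law,
segment lengths are exponential with a calibrated mean, directions jitter
around the parent direction, radii taper toward the tips, and segments
carry a gentle Brownian-bridge tortuosity.  The population mean length per
cell is calibrated once per condition (on a fixed internal sample) so that
realized means match the configured target; one fixed-point step suffices
because realized length is homogeneous of degree one in the length scale.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import ParameterError
from .geometry import (
    clip_polyline_to_box,
    orthonormal_frame,
    polyline_length,
    random_unit_vector,
)
from .units import lv_to_paper_units, nv_to_paper_units

__all__ = [
    "ConditionParams",
    "CONTROL",
    "DEAFFERENTED",
    "CONDITIONS",
    "SomaModel",
    "Segment",
    "ProcessArbor",
    "Cell",
    "TissueBlock",
    "SectionModel",
    "build_tissue",
    "sample_soma",
    "grow_arbor",
    "arbor_total_length",
    "cut_sections",
    "to_swc",
]


@dataclass(frozen=True)
class ConditionParams:
    """Generator parameters for one experimental regime.

    Densities are in cells/mm^3, lengths in um.  ``length_per_cell_um`` is
    the target mean total process length per cell; the segment-length scale
    is calibrated so realized means match it.  ``orientation_anisotropy``
    in [0, 1) biases primary directions away from the vertical (y) axis,
    emulating the tangential orientation of superficial-lamina cells; it is
    off by default.
    """

    name: str
    nv_per_mm3: float
    length_per_cell_um: float
    soma_volume_mean_um3: float
    soma_volume_sd_um3: float
    primary_mean: float
    primary_sd: float
    segment_length_um: float
    branch_prob: float
    max_depth: int
    branch_angle_deg: float = 40.0
    direction_jitter_deg: float = 15.0
    tortuosity: float = 0.12
    points_per_segment: int = 7
    root_radius_um: float = 0.6
    tip_radius_um: float = 0.04
    radius_jitter_sd: float = 0.15  # lognormal per-cell caliber spread
    soma_aspect_sd: float = 0.2
    orientation_anisotropy: float = 0.0


#: Quiescent regime: N_V 10^4 /mm^3, 800 um of process per cell
#: (length density 8,000 mm/mm^3), somata 149 +- 74 um^3, ~4 primaries.
CONTROL = ConditionParams(
    name="control",
    nv_per_mm3=10_000.0,
    length_per_cell_um=800.0,
    soma_volume_mean_um3=149.0,
    soma_volume_sd_um3=74.0,
    primary_mean=4.1,
    primary_sd=1.2,
    segment_length_um=11.0,
    branch_prob=0.85,
    max_depth=4,
    root_radius_um=0.6,
)

#: Reactive regime at the microgliosis peak: x5 cell density, half the
#: process length per cell (density 20,000 mm/mm^3), larger somata
#: (249 +- 118 um^3), ~9 shorter, thicker primaries.
DEAFFERENTED = ConditionParams(
    name="deafferented",
    nv_per_mm3=50_000.0,
    length_per_cell_um=400.0,
    soma_volume_mean_um3=249.0,
    soma_volume_sd_um3=118.0,
    primary_mean=9.0,
    primary_sd=2.0,
    segment_length_um=9.5,
    branch_prob=0.55,
    max_depth=3,
    root_radius_um=0.9,
    tip_radius_um=0.02,
)

CONDITIONS = {"control": CONTROL, "deafferented": DEAFFERENTED}


# --------------------------------------------------------------------------
# domain types


@dataclass
class SomaModel:
    """Ellipsoidal cell body: center, semi-axes and orientation (um)."""

    center: np.ndarray
    semi_axes: np.ndarray
    rotation: np.ndarray  # 3x3 matrix, soma frame -> world

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if np.any(self.semi_axes <= 0):
            raise ParameterError("soma semi-axes must be positive")

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return float(4.0 / 3.0 * np.pi * a * b * c)

    def quadric(self) -> np.ndarray:
        """Matrix A with the surface defined by (x-c)^T A (x-c) = 1."""
        d = np.diag(1.0 / self.semi_axes**2)
        return self.rotation @ d @ self.rotation.T

    def surface_point(self, direction: np.ndarray) -> np.ndarray:
        """Point where the ray from the center along ``direction`` exits."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        t = 1.0 / np.sqrt(d @ self.quadric() @ d)
        return self.center + t * d


@dataclass
class Segment:
    """One branch-order segment: polyline vertices with per-vertex radii."""

    parent: int  # index of parent segment, -1 for primaries (soma-attached)
    points: np.ndarray
    radii: np.ndarray

    @property
    def length(self) -> float:
        return polyline_length(self.points)


@dataclass
class ProcessArbor:
    """Tree of process segments rooted on the soma surface."""

    segments: list[Segment] = field(default_factory=list)

    @property
    def primary_count(self) -> int:
        return sum(1 for s in self.segments if s.parent == -1)

    def total_length(self) -> float:
        return float(sum(s.length for s in self.segments))

    def validate(self, soma: SomaModel | None = None, atol: float = 1e-6) -> None:
        """Check tree structure and attachment invariants; raise on failure."""
        for i, seg in enumerate(self.segments):
            if seg.parent >= i:
                raise ValueError(f"segment {i} references a later parent (cycle)")
            if len(seg.points) != len(seg.radii):
                raise ValueError(f"segment {i}: points/radii mismatch")
            if seg.parent >= 0:
                tail = self.segments[seg.parent].points[-1]
                if not np.allclose(seg.points[0], tail, atol=atol):
                    raise ValueError(f"segment {i} detached from its parent")
            elif soma is not None:
                p = seg.points[0] - soma.center
                q = float(p @ soma.quadric() @ p)
                if abs(q - 1.0) > 1e-3:
                    raise ValueError(f"primary {i} does not start on the soma surface")


@dataclass
class Cell:
    soma: SomaModel
    arbor: ProcessArbor


@dataclass
class TissueBlock:
    """A rectangular block of synthetic tissue with exact ground truth.

    The reference space is [0, dims).  With ``halo_um > 0`` cells are also
    generated in a margin around it, so that curve density inside the
    reference space is homogeneous (no edge depletion from arbors of
    unsimulated neighbours); densities and counts always refer to cells
    whose centroid lies in the reference space.
    """

    dims: np.ndarray  # (x, y, z) extents, um
    cells: list[Cell]
    condition: ConditionParams
    seed: int
    halo_um: float = 0.0

    def __post_init__(self):
        self.dims = np.asarray(self.dims, dtype=float)

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.dims))

    @property
    def n_cells(self) -> int:
        """Cells with centroid inside the reference space."""
        if self.halo_um == 0.0:
            return len(self.cells)
        return int(self.in_core().sum())

    @property
    def n_cells_total(self) -> int:
        return len(self.cells)

    def in_core(self) -> np.ndarray:
        c = self.soma_centroids()
        if not len(c):
            return np.zeros(0, dtype=bool)
        return np.all((c >= 0.0) & (c < self.dims), axis=1)

    def nv_per_mm3(self) -> float:
        """Realized numerical density (soma centroids per mm^3)."""
        return nv_to_paper_units(self.n_cells / self.volume_um3)

    def soma_centroids(self) -> np.ndarray:
        if not self.cells:
            return np.zeros((0, 3))
        return np.array([c.soma.center for c in self.cells])

    def curves(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """All process segments as (points, radii) polylines."""
        out = []
        for cell in self.cells:
            for seg in cell.arbor.segments:
                out.append((seg.points, seg.radii))
        return out

    def clipped_total_length(self, lo=None, hi=None) -> float:
        """Exact process length inside [lo, hi] (default: the block)."""
        lo = np.zeros(3) if lo is None else np.asarray(lo, dtype=float)
        hi = self.dims if hi is None else np.asarray(hi, dtype=float)
        total = 0.0
        for pts, rad in self.curves():
            for run, _ in clip_polyline_to_box(pts, lo, hi, rad):
                total += polyline_length(run)
        return total

    def lv_mm_per_mm3(self) -> float:
        """Ground-truth length density (clipped to the block), mm/mm^3."""
        return lv_to_paper_units(self.clipped_total_length() / self.volume_um3)

    def per_cell_table(self) -> pd.DataFrame:
        core = self.in_core() if self.cells else np.zeros(0, dtype=bool)
        rows = []
        for i, cell in enumerate(self.cells):
            rows.append(
                {
                    "cell": i,
                    "x": cell.soma.center[0],
                    "y": cell.soma.center[1],
                    "z": cell.soma.center[2],
                    "in_reference_space": bool(core[i]) if self.halo_um else True,
                    "soma_volume_um3": cell.soma.volume,
                    "total_length_um": cell.arbor.total_length(),
                    "primary_count": cell.arbor.primary_count,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "cell",
                "x",
                "y",
                "z",
                "in_reference_space",
                "soma_volume_um3",
                "total_length_um",
                "primary_count",
            ],
        )

    def ground_truth(self) -> dict:
        """Block-level summary for JSON export."""
        table = self.per_cell_table()
        if len(table):
            table = table[table["in_reference_space"]]
        return {
            "condition": self.condition.name,
            "seed": self.seed,
            "dims_um": self.dims.tolist(),
            "halo_um": self.halo_um,
            "n_cells": self.n_cells,
            "nv_per_mm3": self.nv_per_mm3(),
            "total_length_in_block_um": self.clipped_total_length(),
            "lv_mm_per_mm3": self.lv_mm_per_mm3(),
            "mean_length_per_cell_um": (
                float(table["total_length_um"].mean()) if self.n_cells else 0.0
            ),
            "mean_soma_volume_um3": (
                float(table["soma_volume_um3"].mean()) if self.n_cells else 0.0
            ),
            "mean_primary_count": (
                float(table["primary_count"].mean()) if self.n_cells else 0.0
            ),
        }

    def export_ground_truth(self, json_path, csv_path=None) -> None:
        with open(json_path, "w") as fh:
            json.dump(self.ground_truth(), fh, indent=2)
        if csv_path is not None:
            self.per_cell_table().to_csv(csv_path, index=False)


@dataclass
class SectionModel:
    """A cut histological section: clipped geometry in section coordinates.

    z runs from 0 at the section bottom to ``measured_thickness``
    (= nominal thickness x z_shrinkage) at the top; x/y are unchanged.
    """

    index: int
    z_lo: float  # nominal position of the slab in block coordinates
    z_hi: float
    xy_dims: np.ndarray
    nominal_thickness: float
    z_shrinkage: float
    curves: list[tuple[np.ndarray, np.ndarray]]
    soma_points: np.ndarray
    soma_volumes: np.ndarray
    cell_indices: np.ndarray

    @property
    def measured_thickness(self) -> float:
        return self.nominal_thickness * self.z_shrinkage

    def total_curve_length(self) -> float:
        return float(sum(polyline_length(p) for p, _ in self.curves))


# --------------------------------------------------------------------------
# generation


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalized Gaussian quaternion."""
    q = rng.normal(size=4)
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _tilted(direction, angle_deg, azimuth, rng=None) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    u, v = orthonormal_frame(d)
    th = np.deg2rad(angle_deg)
    nd = np.cos(th) * d + np.sin(th) * (np.cos(azimuth) * u + np.sin(azimuth) * v)
    return nd / np.linalg.norm(nd)


def grow_arbor(
    rng: np.random.Generator,
    params: ConditionParams,
    soma: SomaModel,
    length_scale: float = 1.0,
) -> ProcessArbor:
    """Grow one process arbor on ``soma``.

    Primaries start on the soma surface along near-uniform directions; each
    segment either terminates or (below ``max_depth``, with probability
    ``branch_prob``) splits into two children tilted away from the parent
    direction.  ``length_scale`` multiplies the mean segment length and the
    (proportional) tortuosity amplitude, so total length scales linearly.
    """
    shape = (params.primary_mean / params.primary_sd) ** 2
    scale_g = params.primary_sd**2 / params.primary_mean
    n_primaries = int(np.round(rng.gamma(shape, scale_g)))
    segments: list[Segment] = []
    stack: list[tuple[np.ndarray, np.ndarray, int, int]] = []

    for _ in range(max(0, n_primaries)):
        d = random_unit_vector(rng)
        if params.orientation_anisotropy > 0.0:
            d = d.copy()
            d[1] *= 1.0 - params.orientation_anisotropy
            d /= np.linalg.norm(d)
        stack.append((soma.surface_point(d), d, 0, -1))

    # radius tapers geometrically from root to tip across branch orders
    # (a segment at depth k spans the (k, k+1)/(max_depth+1) stretch),
    # with a per-cell caliber factor so population radii are continuous
    levels = params.max_depth + 1
    ratio = params.tip_radius_um / params.root_radius_um
    caliber = float(rng.lognormal(0.0, params.radius_jitter_sd))
    depth_radius = (
        caliber
        * params.root_radius_um
        * ratio ** (np.arange(levels + 1) / levels)
    )

    m = params.points_per_segment
    ts = np.linspace(0.0, 1.0, m)
    while stack:
        start, d, depth, parent = stack.pop()
        mean_len = params.segment_length_um * length_scale
        seg_len = min(rng.exponential(mean_len), 4.0 * mean_len)
        base = start + np.outer(ts * seg_len, d)
        u, v = orthonormal_frame(d)
        # Brownian-bridge wiggle orthogonal to the chord; amplitude
        # proportional to segment length keeps the scaling exact.
        w = np.vstack([np.zeros((1, 2)), np.cumsum(rng.normal(size=(m - 1, 2)), axis=0)])
        w = w - np.outer(ts, w[-1])
        w = w * (params.tortuosity * seg_len / np.sqrt(m))
        pts = base + np.outer(w[:, 0], u) + np.outer(w[:, 1], v)
        pts[0] = start
        radii = np.linspace(depth_radius[depth], depth_radius[depth + 1], m)
        idx = len(segments)
        segments.append(Segment(parent, pts, radii))
        if depth < params.max_depth and rng.uniform() < params.branch_prob:
            azim = rng.uniform(0.0, 2.0 * np.pi)
            for off in (0.0, np.pi):
                ang = params.branch_angle_deg + rng.normal(0.0, params.direction_jitter_deg)
                child_dir = _tilted(d, ang, azim + off)
                stack.append((pts[-1], child_dir, depth + 1, idx))
    return ProcessArbor(segments)


def arbor_total_length(arbor: ProcessArbor) -> float:
    """Exact total length of an arbor (sum of segment polyline lengths)."""
    return arbor.total_length()


_CALIBRATION_SEED = 12345
_CALIBRATION_N = 800


@lru_cache(maxsize=None)
def _length_scale(params: ConditionParams) -> float:
    """Segment-length scale so the mean per-cell length hits its target.

    Fitted on a fixed internal sample; exact in expectation because arbor
    length is homogeneous of degree one in the scale.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    r = (3.0 * params.soma_volume_mean_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    soma = SomaModel(np.zeros(3), np.full(3, r), np.eye(3))
    total = 0.0
    for _ in range(_CALIBRATION_N):
        total += grow_arbor(rng, params, soma, 1.0).total_length()
    realized = total / _CALIBRATION_N
    if realized <= 0:
        return 1.0
    return params.length_per_cell_um / realized


def build_tissue(
    params: ConditionParams,
    dims,
    seed: int,
    with_arbors: bool = True,
    calibrate: bool = True,
    halo_um: float = 0.0,
) -> TissueBlock:
    """Generate a tissue block under one condition regime.

    Soma centers follow a homogeneous Poisson process of the configured
    intensity; soma volumes are lognormal with the configured mean/sd.
    ``halo_um`` extends the generated volume beyond the reference space on
    all sides so that process density inside it is free of edge depletion
    (a 70 um halo covers ~95% of arbor reach).  ``with_arbors=False``
    skips process growth (fast, for counting-only experiments).
    Identical ``(params, dims, seed, halo_um)`` give bit-identical blocks.
    """
    dims = np.asarray(dims, dtype=float)
    if np.any(dims <= 0) or halo_um < 0:
        raise ParameterError("block dimensions must be positive")
    if params.nv_per_mm3 < 0:
        raise ParameterError("cell density must be non-negative")
    rng = np.random.default_rng(seed)
    lam = params.nv_per_mm3 * 1e-9  # cells per um^3
    ext = dims + 2.0 * halo_um
    n = int(rng.poisson(lam * np.prod(ext)))
    centers = rng.uniform(0.0, 1.0, size=(n, 3)) * ext - halo_um
    scale = _length_scale(params) if (calibrate and with_arbors) else 1.0

    cells = []
    for i in range(n):
        soma = sample_soma(rng, params, centers[i])
        arbor = (
            grow_arbor(rng, params, soma, scale) if with_arbors else ProcessArbor([])
        )
        cells.append(Cell(soma, arbor))
    return TissueBlock(dims, cells, params, seed, halo_um=halo_um)


def sample_soma(rng: np.random.Generator, params: ConditionParams, center) -> SomaModel:
    """Draw one soma: lognormal volume, mild aspect spread, random pose."""
    mu, sig = _lognormal_params(params.soma_volume_mean_um3, params.soma_volume_sd_um3)
    vol = float(rng.lognormal(mu, sig))
    aspects = rng.lognormal(0.0, params.soma_aspect_sd, size=3)
    c0 = (3.0 * vol / (4.0 * np.pi * np.prod(aspects))) ** (1.0 / 3.0)
    return SomaModel(np.asarray(center, dtype=float), aspects * c0, _random_rotation(rng))


# --------------------------------------------------------------------------
# sectioning


def cut_sections(
    block: TissueBlock,
    thickness: float = 40.0,
    period: int = 5,
    z_shrinkage: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[SectionModel]:
    """Cut the block into serial coronal slabs and keep every ``period``-th.

    The sampled series starts at a uniformly random slab index in
    [0, period).  Geometry is clipped to each slab and z is rescaled by
    ``z_shrinkage`` (processing collapse along the optical axis); the
    nominal cut thickness is retained as metadata so that density
    estimates can be referred back to the cut (pre-collapse) volume.
    """
    if period < 1 or int(period) != period:
        raise ParameterError("period must be a positive integer")
    if not (0.0 < z_shrinkage <= 1.0):
        raise ParameterError("z_shrinkage must be in (0, 1]")
    if thickness <= 0 or thickness > block.dims[2]:
        raise ParameterError("thickness must be positive and fit in the block")
    if rng is None:
        rng = np.random.default_rng(block.seed + 1)

    n_slabs = int(block.dims[2] // thickness)
    start = int(rng.integers(period))
    lo_xy = np.zeros(2)
    sections = []
    curves = block.curves()
    centroids = block.soma_centroids()
    volumes = np.array([c.soma.volume for c in block.cells]) if block.cells else np.zeros(0)
    for j in range(start, n_slabs, int(period)):
        z_lo, z_hi = j * thickness, (j + 1) * thickness
        lo = np.array([0.0, 0.0, z_lo])
        hi = np.array([block.dims[0], block.dims[1], z_hi])
        sec_curves = []
        for pts, rad in curves:
            for run, run_rad in clip_polyline_to_box(pts, lo, hi, rad):
                shifted = run.copy()
                shifted[:, 2] = (shifted[:, 2] - z_lo) * z_shrinkage
                sec_curves.append((shifted, run_rad))
        if len(centroids):
            in_slab = (centroids[:, 2] >= z_lo) & (centroids[:, 2] < z_hi)
            pts = centroids[in_slab].copy()
            pts[:, 2] = (pts[:, 2] - z_lo) * z_shrinkage
            vols = volumes[in_slab]
            idx = np.nonzero(in_slab)[0]
        else:
            pts = np.zeros((0, 3))
            vols = np.zeros(0)
            idx = np.zeros(0, dtype=int)
        sections.append(
            SectionModel(
                index=j,
                z_lo=z_lo,
                z_hi=z_hi,
                xy_dims=block.dims[:2].copy(),
                nominal_thickness=thickness,
                z_shrinkage=z_shrinkage,
                curves=sec_curves,
                soma_points=pts,
                soma_volumes=vols,
                cell_indices=idx,
            )
        )
    if not sections:
        warnings.warn("no sections sampled (block thinner than one slab period)")
    return sections


# --------------------------------------------------------------------------
# export


def to_swc(cell: Cell, cell_id: int = 0) -> str:
    """SWC-like text export of one cell (soma point + process vertices)."""
    lines = [f"# stereoglia cell {cell_id}", "# id type x y z radius parent"]
    x, y, z = cell.soma.center
    r = float(np.mean(cell.soma.semi_axes))
    lines.append(f"1 1 {x:.3f} {y:.3f} {z:.3f} {r:.3f} -1")
    next_id = 2
    seg_tail_ids: dict[int, int] = {}
    for si, seg in enumerate(cell.arbor.segments):
        parent_id = 1 if seg.parent == -1 else seg_tail_ids[seg.parent]
        for vi in range(len(seg.points)):
            if vi == 0 and seg.parent >= 0:
                continue  # shared vertex with the parent tail
            px, py, pz = seg.points[vi]
            pr = seg.radii[vi]
            lines.append(f"{next_id} 3 {px:.3f} {py:.3f} {pz:.3f} {pr:.3f} {parent_id}")
            parent_id = next_id
            next_id += 1
        seg_tail_ids[si] = parent_id
    return "\n".join(lines) + "\n"
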