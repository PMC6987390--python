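"""Rendering of section models into calibrated image stacks.

A section's process curves (and optionally somata) are rasterized into a
voxel grid under a simple confocal-like model: centerline splatting with
radius-dependent intensity, optional Gaussian blur (PSF width in um) and
additive Gaussian noise.  The "dab" modality models chromogenic
immunostaining's lower sensitivity to very thin processes by dropping
sub-threshold-radius stretches before rasterization; "if" (fluorescence)
renders everything.  Stacks can be rotated about the vertical (y) axis and
maximum-projected for the vertical-projection length protocol, and
projections binarized/skeletonized for image-mode crossing counts.

The detection threshold is not hand-set: ``calibrate_detection_threshold``
derives it from a calibration tissue sample as the radius below which the
target fraction of process length lies.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .errors import ParameterError
from .morphology import SectionModel

__all__ = [
    "ImageStack",
    "Projection2D",
    "render_stack",
    "rotate_and_project",
    "binarize_and_skeletonize",
    "apply_detection",
    "calibrate_detection_threshold",
]


@dataclass
class ImageStack:
    """Calibrated voxel grid, indexed (z, y, x); vertical axis is y."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]  # (dx, dy, dz), um
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    nominal_depth_um: float = 0.0
    vertical_axis: str = "y"

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel size must be positive")
        if np.any(~np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ParameterError("intensities must be finite and non-negative")

    @property
    def depth_um(self) -> float:
        return self.voxels.shape[0] * self.voxel_size[2]

    def save_tiff(self, path) -> None:
        dx, dy, dz = self.voxel_size
        tifffile.imwrite(
            path,
            self.voxels.astype(np.float32),
            imagej=True,
            resolution=(1.0 / dx, 1.0 / dy),
            metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
        )

    @classmethod
    def load_tiff(cls, path, voxel_size=None) -> "ImageStack":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            if voxel_size is None:
                meta = tf.imagej_metadata or {}
                dz = float(meta.get("spacing", 1.0))
                tags = tf.pages[0].tags
                xr = tags.get("XResolution")
                dx = xr.value[1] / xr.value[0] if xr else 1.0
                voxel_size = (dx, dx, dz)
        if data.ndim == 2:
            data = data[None]
        return cls(np.asarray(data, dtype=float), tuple(voxel_size))


@dataclass
class Projection2D:
    """Maximum-intensity projection at a rotation angle about vertical."""

    pixels: np.ndarray  # (ny, nx)
    pixel_size: float
    angle_deg: float
    source: str = ""

    def __post_init__(self):
        self.angle_deg = float(self.angle_deg) % 180.0

    def save_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            self.pixels.astype(np.float32),
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
        )


# --------------------------------------------------------------------------
# detection model


def apply_detection(
    curves,
    radius_threshold: float = 0.0,
    dropout_p: float = 1.0,
    rng: np.random.Generator | None = None,
):
    """Remove thin-process stretches a modality fails to detect.

    Contiguous vertex runs with radius below ``radius_threshold`` are
    dropped with probability ``dropout_p`` (each run decided once).
    Returns a new curve list; with threshold 0 the input passes through.
    """
    if radius_threshold <= 0.0:
        return list(curves)
    out = []
    for pts, rad in curves:
        if rad is None:
            out.append((pts, rad))
            continue
        keep = np.asarray(rad, dtype=float) >= radius_threshold
        if keep.all():
            out.append((pts, rad))
            continue
        # split into kept runs; thin runs survive with prob 1 - dropout_p
        idx = 0
        n = len(keep)
        while idx < n:
            val = keep[idx]
            j = idx
            while j < n and keep[j] == val:
                j += 1
            survives = bool(val) or (
                dropout_p < 1.0
                and rng is not None
                and rng.uniform() >= dropout_p
            )
            if survives and j - idx >= 2:
                out.append((pts[idx:j], rad[idx:j]))
            idx = j
    return out


def calibrate_detection_threshold(curves, missed_fraction: float = 0.30) -> float:
    """Radius below which ``missed_fraction`` of total curve length lies.

    One-time calibration of the chromogenic modality's thin-process loss:
    dropping everything below the returned radius removes (by
    construction) the target fraction of length on the calibration sample.
    """
    if not (0.0 <= missed_fraction < 1.0):
        raise ParameterError("missed_fraction must be in [0, 1)")
    radii = []
    lengths = []
    for pts, rad in curves:
        if rad is None or len(pts) < 2:
            continue
        seg_len = np.linalg.norm(np.diff(np.asarray(pts, float), axis=0), axis=1)
        # a mini-segment survives detection iff both endpoint radii do, so
        # its effective radius is the endpoint minimum
        seg_rad = np.minimum(np.asarray(rad, float)[:-1], np.asarray(rad, float)[1:])
        radii.append(seg_rad)
        lengths.append(seg_len)
    if not radii:
        return 0.0
    radii = np.concatenate(radii)
    lengths = np.concatenate(lengths)
    order = np.argsort(radii)
    sr = radii[order]
    cum = np.cumsum(lengths[order]) / lengths.sum()
    # candidate thresholds are the observed radii (plus one past the max);
    # dropped mass at threshold v is the length strictly below v — pick
    # the candidate whose dropped mass is closest to the target, which
    # stays exact under ties
    uniq, first = np.unique(sr, return_index=True)
    below = np.where(first > 0, cum[np.maximum(first - 1, 0)], 0.0)
    candidates = np.append(uniq, np.nextafter(uniq[-1], np.inf))
    dropped = np.append(below, 1.0)
    return float(candidates[np.argmin(np.abs(dropped - missed_fraction))])


# --------------------------------------------------------------------------
# rendering


def _resample_polyline(pts: np.ndarray, rad: np.ndarray, step: float):
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg_len.sum()
    if total == 0.0:
        return pts[:1], rad[:1]
    n = max(2, int(np.ceil(total / step)))
    s = np.linspace(0.0, total, n)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    out = np.column_stack([np.interp(s, cum, pts[:, k]) for k in range(3)])
    r = np.interp(s, cum, rad) if rad is not None else np.full(n, 0.1)
    return out, r


def render_stack(
    section: SectionModel,
    voxel_size: float = 0.5,
    modality: str = "if",
    psf_sigma: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    radius_threshold: float = 0.0,
    dropout_p: float = 1.0,
    include_somata: bool = True,
    z_range: tuple[float, float] | None = None,
) -> ImageStack:
    """Render a section model into an isotropic-voxel confocal-like stack.

    ``modality="dab"`` applies the thin-process detection loss before
    rasterization (threshold from ``calibrate_detection_threshold``);
    ``z_range`` restricts rendering to a sub-slab (e.g. a 4-um
    vertical-projection substack).  An empty section renders as an
    all-background stack.  Identical seeds give identical stacks.
    """
    if modality not in ("if", "dab"):
        raise ParameterError("modality must be 'if' or 'dab'")
    if voxel_size <= 0:
        raise ParameterError("voxel size must be positive")
    rng = np.random.default_rng(seed)
    z0, z1 = (0.0, section.measured_thickness) if z_range is None else z_range
    nx = max(1, int(np.round(section.xy_dims[0] / voxel_size)))
    ny = max(1, int(np.round(section.xy_dims[1] / voxel_size)))
    nz = max(1, int(np.round((z1 - z0) / voxel_size)))
    vox = np.zeros((nz, ny, nx), dtype=np.float32)

    curves = section.curves
    if modality == "dab":
        curves = apply_detection(curves, radius_threshold, dropout_p, rng)

    step = voxel_size / 2.0
    for pts, rad in curves:
        pts = np.asarray(pts, dtype=float)
        if len(pts) < 2:
            continue
        sp, sr = _resample_polyline(pts, rad, step)
        keep = (sp[:, 2] >= z0) & (sp[:, 2] < z1)
        sp, sr = sp[keep], sr[keep]
        if not len(sp):
            continue
        ix = np.floor(sp[:, 0] / voxel_size).astype(int)
        iy = np.floor(sp[:, 1] / voxel_size).astype(int)
        iz = np.floor((sp[:, 2] - z0) / voxel_size).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
        ix, iy, iz, sr = ix[ok], iy[ok], iz[ok], sr[ok]
        # splat: thin processes hit one voxel; thicker ones a small ball
        rbin = np.round(sr / voxel_size).astype(int)
        for rb in np.unique(rbin):
            sel = rbin == rb
            w = np.maximum(sr[sel], voxel_size / 2.0) ** 2
            if rb == 0:
                np.add.at(vox, (iz[sel], iy[sel], ix[sel]), w.astype(np.float32))
            else:
                offs = _ball_offsets(rb)
                share = (w / len(offs)).astype(np.float32)
                for oz, oy, ox in offs:
                    jz, jy, jx = iz[sel] + oz, iy[sel] + oy, ix[sel] + ox
                    good = (jx >= 0) & (jx < nx) & (jy >= 0) & (jy < ny) & (jz >= 0) & (jz < nz)
                    np.add.at(vox, (jz[good], jy[good], jx[good]), share[good])

    if include_somata and len(section.soma_points):
        _stamp_somata(vox, section, voxel_size, z0, z1)

    if psf_sigma > 0:
        vox = ndimage.gaussian_filter(vox, sigma=psf_sigma / voxel_size)
    if noise_sd > 0:
        vox = vox + rng.normal(0.0, noise_sd, size=vox.shape).astype(np.float32)
        vox = np.clip(vox, 0.0, None)
    return ImageStack(
        voxels=vox,
        voxel_size=(voxel_size, voxel_size, voxel_size),
        nominal_depth_um=z1 - z0,
    )


def _ball_offsets(rb: int):
    offs = []
    for oz in range(-rb, rb + 1):
        for oy in range(-rb, rb + 1):
            for ox in range(-rb, rb + 1):
                if oz * oz + oy * oy + ox * ox <= rb * rb:
                    offs.append((oz, oy, ox))
    return offs


def _stamp_somata(vox, section: SectionModel, voxel_size: float, z0: float, z1: float):
    """Add solid ellipsoidal soma profiles (z compressed by shrinkage)."""
    nz, ny, nx = vox.shape
    k = section.z_shrinkage
    for center, vol in zip(section.soma_points, section.soma_volumes):
        r = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        rz = r * k
        x_lo = max(0, int((center[0] - r) / voxel_size))
        x_hi = min(nx, int(np.ceil((center[0] + r) / voxel_size)) + 1)
        y_lo = max(0, int((center[1] - r) / voxel_size))
        y_hi = min(ny, int(np.ceil((center[1] + r) / voxel_size)) + 1)
        z_lo = max(0, int((center[2] - rz - z0) / voxel_size))
        z_hi = min(nz, int(np.ceil((center[2] + rz - z0) / voxel_size)) + 1)
        if x_lo >= x_hi or y_lo >= y_hi or z_lo >= z_hi:
            continue
        zz, yy, xx = np.meshgrid(
            (np.arange(z_lo, z_hi) + 0.5) * voxel_size + z0,
            (np.arange(y_lo, y_hi) + 0.5) * voxel_size,
            (np.arange(x_lo, x_hi) + 0.5) * voxel_size,
            indexing="ij",
        )
        q = (
            ((xx - center[0]) / r) ** 2
            + ((yy - center[1]) / r) ** 2
            + ((zz - center[2]) / rz) ** 2
        )
        vox[z_lo:z_hi, y_lo:y_hi, x_lo:x_hi] += (q <= 1.0).astype(np.float32)


# --------------------------------------------------------------------------
# projections


def rotate_and_project(stack: ImageStack, angle_deg: float) -> Projection2D:
    """Rotate about the vertical (y) axis and maximum-project along z.

    Rotation uses trilinear interpolation with zero padding; angles are
    normalized modulo 180.  Angle 0 is the plain maximum z-projection.
    Anisotropic stacks are resampled to isotropic voxels first.
    """
    angle = float(angle_deg) % 180.0
    dx, dy, dz = stack.voxel_size
    vox = stack.voxels
    if not np.isclose(dz, dx):
        vox = ndimage.zoom(vox, (dz / dx, 1.0, 1.0), order=1)
    if angle != 0.0:
        # array axes (z, y, x): rotating in the (z, x) plane is a rotation
        # about the vertical axis
        vox = ndimage.rotate(
            vox, angle, axes=(0, 2), reshape=True, order=1, mode="constant", cval=0.0
        )
    pixels = vox.max(axis=0)
    return Projection2D(pixels=pixels, pixel_size=dx, angle_deg=angle)


def binarize_and_skeletonize(
    projection: Projection2D | np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """Threshold (Otsu by default) and thin to a 1-pixel-wide skeleton.

    The skeleton operationalizes the "central spine" of thick processes
    for image-mode crossing counts.  All-background input gives an empty
    skeleton.  Deterministic for fixed input.
    """
    pixels = projection.pixels if isinstance(projection, Projection2D) else projection
    pixels = np.asarray(pixels, dtype=float)
    if pixels.size == 0 or pixels.max() == pixels.min():
        return np.zeros_like(pixels, dtype=bool)
    if threshold is None:
        threshold = threshold_otsu(pixels)
    mask = pixels > threshold
    return skeletonize(mask)
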