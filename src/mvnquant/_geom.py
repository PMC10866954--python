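"""Voxel-grid geometry primitives shared by the synthetic generator and the
quantification modules.

Conventions: arrays are indexed (Z, Y, X); physical coordinates and sizes are
(x, y, z) in micrometres; a voxel with index (k, j, i) has its centre at
((i + 0.5) * vx, (j + 0.5) * vy, (k + 0.5) * vz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi


@dataclass(frozen=True)
class GridSpec:
    """A 3D voxel grid with physical calibration.

    shape is (Z, Y, X) voxels; voxel_size is (x, y, z) in µm.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")

    @property
    def size_um(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in µm."""
        nz, ny, nx = self.shape
        vx, vy, vz = self.voxel_size
        return (nx * vx, ny * vy, nz * vz)

    @property
    def pixel_size(self) -> tuple[float, float]:
        """In-plane (x, y) pixel size in µm, for MIP-level work."""
        return (self.voxel_size[0], self.voxel_size[1])

    @property
    def voxel_volume(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz

    @property
    def pixel_area(self) -> float:
        vx, vy, _ = self.voxel_size
        return vx * vy

    @classmethod
    def for_domain(
        cls,
        domain_um: tuple[float, float, float],
        voxel_size: tuple[float, float, float],
    ) -> "GridSpec":
        vx, vy, vz = voxel_size
        dx, dy, dz = domain_um
        shape = (max(1, round(dz / vz)), max(1, round(dy / vy)), max(1, round(dx / vx)))
        return cls(shape=shape, voxel_size=voxel_size)


# Default acquisition geometry: 20x-objective-like in-plane sampling with a
# coarse (anisotropic) 5 µm Z step, 40 slices.
DEFAULT_VOXEL_SIZE = (0.6, 0.6, 5.0)
DEFAULT_SHAPE = (40, 256, 512)
DEFAULT_GRID = GridSpec(shape=DEFAULT_SHAPE, voxel_size=DEFAULT_VOXEL_SIZE)


def _axis_centers(n: int, v: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * v


def _bbox_range(lo: float, hi: float, v: float, n: int) -> tuple[int, int]:
    """Index range [i0, i1) of voxel centres falling inside [lo, hi]."""
    i0 = max(int(math.floor(lo / v - 0.5)), 0)
    i1 = min(int(math.ceil(hi / v + 0.5)) + 1, n)
    return i0, max(i1, i0)


def capsule_mask(
    grid: GridSpec, a: np.ndarray, b: np.ndarray, radius: float
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Rasterize a capsule (cylinder with hemispherical caps) of given radius
    around segment a→b (µm coordinates).

    Returns (bbox slices in (z, y, x) order, boolean submask). A voxel is
    inside when its centre lies within ``radius`` of the segment.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    vx, vy, vz = grid.voxel_size
    nz, ny, nx = grid.shape
    lo = np.minimum(a, b) - radius
    hi = np.maximum(a, b) + radius
    ix0, ix1 = _bbox_range(lo[0], hi[0], vx, nx)
    iy0, iy1 = _bbox_range(lo[1], hi[1], vy, ny)
    iz0, iz1 = _bbox_range(lo[2], hi[2], vz, nz)
    sl = (slice(iz0, iz1), slice(iy0, iy1), slice(ix0, ix1))
    if ix1 <= ix0 or iy1 <= iy0 or iz1 <= iz0:
        return sl, np.zeros((max(iz1 - iz0, 0), max(iy1 - iy0, 0), max(ix1 - ix0, 0)), bool)

    xs = _axis_centers(nx, vx)[ix0:ix1][None, None, :]
    ys = _axis_centers(ny, vy)[iy0:iy1][None, :, None]
    zs = _axis_centers(nz, vz)[iz0:iz1][:, None, None]

    d = b - a
    l2 = float(np.dot(d, d))
    px = xs - a[0]
    py = ys - a[1]
    pz = zs - a[2]
    if l2 == 0.0:
        dist2 = px * px + py * py + pz * pz
    else:
        t = (px * d[0] + py * d[1] + pz * d[2]) / l2
        np.clip(t, 0.0, 1.0, out=t)
        dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
    return sl, dist2 <= radius * radius


def sphere_mask(
    grid: GridSpec, center: np.ndarray, radius: float
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    c = np.asarray(center, dtype=float)
    return capsule_mask(grid, c, c, radius)


def ellipsoid_mask(
    grid: GridSpec, center: np.ndarray, radii_um: tuple[float, float, float]
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Axis-aligned ellipsoid with semi-axes (rx, ry, rz) µm."""
    c = np.asarray(center, dtype=float)
    rx, ry, rz = radii_um
    vx, vy, vz = grid.voxel_size
    nz, ny, nx = grid.shape
    ix0, ix1 = _bbox_range(c[0] - rx, c[0] + rx, vx, nx)
    iy0, iy1 = _bbox_range(c[1] - ry, c[1] + ry, vy, ny)
    iz0, iz1 = _bbox_range(c[2] - rz, c[2] + rz, vz, nz)
    sl = (slice(iz0, iz1), slice(iy0, iy1), slice(ix0, ix1))
    if ix1 <= ix0 or iy1 <= iy0 or iz1 <= iz0:
        return sl, np.zeros((max(iz1 - iz0, 0), max(iy1 - iy0, 0), max(ix1 - ix0, 0)), bool)
    xs = (_axis_centers(nx, vx)[ix0:ix1][None, None, :] - c[0]) / rx
    ys = (_axis_centers(ny, vy)[iy0:iy1][None, :, None] - c[1]) / ry
    zs = (_axis_centers(nz, vz)[iz0:iz1][:, None, None] - c[2]) / rz
    return sl, xs * xs + ys * ys + zs * zs <= 1.0


def paste(target: np.ndarray, sl: tuple[slice, ...], sub: np.ndarray) -> None:
    """OR a boolean submask into a boolean array (or add for int arrays)."""
    if sub.size == 0:
        return
    if target.dtype == bool:
        target[sl] |= sub
    else:
        target[sl] += sub


def disk_footprint(radius_px: int) -> np.ndarray:
    """Euclidean disk structuring element of the given pixel radius."""
    r = int(radius_px)
    if r <= 0:
        return np.ones((1, 1), bool)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return xx * xx + yy * yy <= r * r


def dilate_um(mask: np.ndarray, border_um: float, pixel_size: tuple[float, float]) -> np.ndarray:
    """Dilate a 2D mask by a physical border, as a Euclidean disk of radius
    ceil(border / pixel size) pixels. border 0 returns the mask unchanged."""
    if border_um <= 0:
        return mask.astype(bool)
    px = min(pixel_size)
    r = int(math.ceil(border_um / px))
    return ndi.binary_dilation(mask, structure=disk_footprint(r))
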