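"""3D stack quantification: denoising, three-class segmentation with
watershed splitting of fused objects, random-walk vascular segmentation,
an optional random-forest pixel-classifier refinement stage, and
object-to-vessel proximity metrics (dilation overlap and surface distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_multiotsu
from skimage.measure import marching_cubes
from skimage.morphology import ball, skeletonize
from skimage.restoration import rolling_ball
from skimage.segmentation import random_walker, watershed
from sklearn.ensemble import RandomForestClassifier

from .errors import (
    DegenerateHistogramError,
    GridMismatchError,
    NoVesselError,
    SeedingFailureError,
)


@dataclass
class ObjectLabels3D:
    """Labeled 3D objects of one marker with per-object volumes (µm³)."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    marker: str

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def count(self) -> int:
        return len(self.ids)

    def volumes_um3(self) -> dict[int, float]:
        vx, vy, vz = self.voxel_size
        vol = vx * vy * vz
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): float(c * vol) for i, c in zip(ids, counts)}


@dataclass
class VesselMask3D:
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    mean_diameter_um: float
    skeleton_length_um: float
    skeleton: np.ndarray | None = None


@dataclass
class ProximityRecord:
    object_id: int
    overlap_volume_um3: float | None = None
    surface_distance_um: float | None = None


def denoise_stack(
    stack_channel: np.ndarray,
    gaussian_sigma: float = 1.0,
    ball_radius: int = 50,
) -> np.ndarray:
    """Gaussian smoothing followed by slice-wise rolling-ball background
    subtraction (the anisotropic Z step makes a 3D ball ill-posed).

    The ball's intensity semi-axis scales with the image's dynamic range
    (8-bit-equivalent convention), so the geometry of the subtraction is
    independent of the intensity units.
    """
    img = np.asarray(stack_channel, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("stack contains non-finite voxels")
    if gaussian_sigma < 0 or ball_radius <= 0:
        raise ValueError("gaussian_sigma must be >= 0 and ball_radius > 0")
    if gaussian_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=(0, gaussian_sigma, gaussian_sigma))
    rng_int = float(img.max() - img.min())
    scale = 255.0 / rng_int if rng_int > 0 else 1.0
    out = np.empty_like(img)
    for k in range(img.shape[0]):
        bg = rolling_ball(img[k] * scale, radius=ball_radius) / scale
        out[k] = img[k] - bg
    return np.clip(out, 0.0, None)


def _multiotsu_cuts(img: np.ndarray) -> tuple[float, float]:
    vals = img[np.isfinite(img)]
    if vals.size == 0 or float(vals.max() - vals.min()) < 1e-12:
        raise DegenerateHistogramError("multi-otsu on a constant image")
    try:
        lo, hi = threshold_multiotsu(vals, classes=3)
    except ValueError as err:
        raise DegenerateHistogramError(str(err)) from err
    return float(lo), float(hi)


def _split_watershed(
    fg: np.ndarray,
    voxel_size: tuple[float, float, float],
    min_peak_distance: int = 3,
) -> np.ndarray:
    """Split fused objects with a distance-transform watershed. Seeds are
    local EDT maxima with a minimum voxel separation; contiguous peak
    plateaus merge into one marker. Deterministic."""
    if not fg.any():
        return np.zeros(fg.shape, np.int32)
    vx, vy, vz = voxel_size
    dist = ndi.distance_transform_edt(fg, sampling=(vz, vy, vx))
    side = 2 * min_peak_distance + 1
    # suppression window: min_peak_distance in-plane, one slice either way in
    # Z (the Z step is coarse relative to the in-plane pixel size)
    foot = np.ones((3, side, side), bool)
    peaks = fg & (dist >= ndi.maximum_filter(dist, footprint=foot))
    # a flat EDT plateau is one connected peak region -> one marker
    markers, n = ndi.label(peaks)
    # every foreground component must own at least one marker
    comps, nc = ndi.label(fg)
    marked = np.unique(comps[peaks]) if n else np.array([], int)
    missing = sorted(set(range(1, nc + 1)) - set(int(m) for m in marked))
    if missing:
        slices = ndi.find_objects(comps)
        for c in missing:
            sl = slices[c - 1]
            local = np.where(comps[sl] == c, dist[sl], -1.0)
            idx = np.unravel_index(int(np.argmax(local)), local.shape)
            n += 1
            markers[tuple(s.start + i for s, i in zip(sl, idx))] = n
    if n == 0:
        markers, _ = ndi.label(fg)
        return markers.astype(np.int32)
    return watershed(-dist, markers, mask=fg).astype(np.int32)


def segment_objects_3class(
    stack_channel: np.ndarray,
    marker: str,
    voxel_size: tuple[float, float, float],
    *,
    min_volume_um3: float = 50.0,
) -> ObjectLabels3D:
    """Three-class multi-Otsu segmentation of a denoised channel.

    The top intensity class is foreground (markers are bright on dark);
    morphological closing then opening (ball radius 1) regularizes it, and a
    distance-transform watershed splits fused objects.
    """
    img = np.asarray(stack_channel, dtype=float)
    _, hi = _multiotsu_cuts(img)
    fg = img >= hi
    if fg.any():
        # radius-1 regularization in-plane only: with a coarse Z step a 3D
        # ball(1) erosion (5 µm in Z) would delete thin bodies outright
        selem = ball(1)[1][None, :, :]
        fg = ndi.binary_closing(fg, structure=selem)
        fg = ndi.binary_opening(fg, structure=selem)
    if not fg.any():
        return ObjectLabels3D(np.zeros(img.shape, np.int32), voxel_size, marker)
    labels = _split_watershed(fg, voxel_size)
    # drop specks below the volume floor
    vx, vy, vz = voxel_size
    voxvol = vx * vy * vz
    min_vox = max(1, int(round(min_volume_um3 / voxvol)))
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = np.zeros(labels.max() + 1, np.int32)
    nxt = 1
    for i, c in zip(ids, counts):
        if c >= min_vox:
            keep[i] = nxt
            nxt += 1
    return ObjectLabels3D(keep[labels], voxel_size, marker)


def _skeleton_length_um(
    skel: np.ndarray, voxel_size: tuple[float, float, float]
) -> float:
    """Total physical length of a 3D skeleton: sum of distances between
    26-connected skeleton voxel pairs (each pair counted once)."""
    vx, vy, vz = voxel_size
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return 0.0
    if len(coords) == 1:
        return float(min(vx, vy))
    occupied = set(map(tuple, coords))
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) > (0, 0, 0):
                    offsets.append((dz, dy, dx))
    total = 0.0
    for dz, dy, dx in offsets:
        step = math.sqrt((dx * vx) ** 2 + (dy * vy) ** 2 + (dz * vz) ** 2)
        for z, y, x in coords:
            if (z + dz, y + dy, x + dx) in occupied:
                total += step
    return total


def segment_vasculature_random_walk(
    stack_channel: np.ndarray,
    voxel_size: tuple[float, float, float],
    *,
    beta: float = 130.0,
) -> VesselMask3D:
    """Random-walk vascular segmentation of a denoised channel.

    Voxels above the upper three-class multi-Otsu cut seed the vessel label,
    voxels below the lower cut seed background, and the random walker assigns
    the remainder. Mean diameter derives from mask volume and 3D skeleton
    length assuming an area-equivalent circular cross-section:
    d̄ = 2·sqrt(V / (π·L)).
    """
    img = np.asarray(stack_channel, dtype=float)
    lo, hi = _multiotsu_cuts(img)
    vessel_seeds = img >= hi
    bg_seeds = img < lo
    if not vessel_seeds.any() or not bg_seeds.any():
        if vessel_seeds.all():
            mask = np.ones(img.shape, bool)
            return _vessel_mask_with_geometry(mask, voxel_size)
        raise SeedingFailureError(
            "could not seed both vessel and background labels from multi-Otsu cuts"
        )
    labels = np.zeros(img.shape, np.int32)
    labels[bg_seeds] = 1
    labels[vessel_seeds] = 2
    if (labels > 0).all():
        mask = labels == 2
    else:
        rw = random_walker(img, labels, beta=beta, mode="cg_j")
        mask = rw == 2
    return _vessel_mask_with_geometry(mask, voxel_size)


def _vessel_mask_with_geometry(
    mask: np.ndarray, voxel_size: tuple[float, float, float]
) -> VesselMask3D:
    if not mask.any():
        raise NoVesselError("random-walk segmentation produced an empty vessel mask")
    vx, vy, vz = voxel_size
    volume = float(mask.sum()) * vx * vy * vz
    skel = skeletonize(mask)
    length = _skeleton_length_um(skel, voxel_size)
    if length <= 0:
        length = max(vx, vy)
    diameter = 2.0 * math.sqrt(volume / (math.pi * length))
    return VesselMask3D(
        mask=mask,
        voxel_size=voxel_size,
        mean_diameter_um=diameter,
        skeleton_length_um=length,
        skeleton=skel,
    )


# --------------------------------------------------------------------------
# Pixel-classifier refinement (random forest on multi-scale features)
# --------------------------------------------------------------------------


@dataclass
class PixelClassifier:
    model: RandomForestClassifier
    sigmas: tuple[float, ...]
    threshold: float = 0.5
    meta: dict = field(default_factory=dict)


def _voxel_features(img: np.ndarray, sigmas: tuple[float, ...]) -> np.ndarray:
    """Per-voxel features: raw intensity plus Gaussian intensity, gradient
    magnitude and Laplacian at each scale (σ in px, in-plane)."""
    img = np.asarray(img, dtype=np.float32)
    feats = [img]
    for s in sigmas:
        sig = (0, s, s) if img.ndim == 3 else s
        feats.append(ndi.gaussian_filter(img, sig))
        feats.append(ndi.gaussian_gradient_magnitude(img, sig if img.ndim != 3 else (0.5, s, s)))
        feats.append(ndi.gaussian_laplace(img, sig if img.ndim != 3 else (0.5, s, s)))
    return np.stack([f.ravel() for f in feats], axis=1)


def train_pixel_classifier(
    stacks: list[np.ndarray],
    masks: list[np.ndarray],
    seed: int,
    *,
    sigmas: tuple[float, ...] = (1.0, 2.0, 4.0),
    n_samples_per_stack: int = 50_000,
    n_estimators: int = 50,
) -> PixelClassifier:
    """Train a seeded random-forest voxel classifier from (stack, mask)
    pairs — e.g. curated segmentation masks — to segment unseen stacks."""
    if not stacks or len(stacks) != len(masks):
        raise ValueError("need >= 1 (stack, mask) training pair of equal length")
    xs, ys = [], []
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    for stack, mask in zip(stacks, masks):
        if stack.shape != mask.shape:
            raise GridMismatchError(
                f"stack {stack.shape} and mask {mask.shape} differ in shape"
            )
        feats = _voxel_features(stack, sigmas)
        target = np.asarray(mask).ravel().astype(np.int8)
        n = feats.shape[0]
        take = min(n_samples_per_stack, n)
        idx = rng.choice(n, size=take, replace=False)
        xs.append(feats[idx])
        ys.append(target[idx])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        random_state=int(seed) & 0x7FFFFFFF,
        n_jobs=1,
        min_samples_leaf=2,
    )
    model.fit(x, y)
    return PixelClassifier(model=model, sigmas=sigmas, meta={"seed": int(seed)})


def apply_pixel_classifier(handle: PixelClassifier, stack: np.ndarray) -> np.ndarray:
    """Predict a binary mask for an unseen stack."""
    feats = _voxel_features(stack, handle.sigmas)
    proba = handle.model.predict_proba(feats)
    classes = list(handle.model.classes_)
    if 1 not in classes:
        return np.zeros(stack.shape, bool)
    p1 = proba[:, classes.index(1)]
    return (p1 >= handle.threshold).reshape(stack.shape)


# --------------------------------------------------------------------------
# Proximity metrics
# --------------------------------------------------------------------------


def proximity_overlap(
    objects: ObjectLabels3D,
    vessels: VesselMask3D,
    dilation_px: int = 3,
) -> list[ProximityRecord]:
    """Overlap volume (µm³) between each object and the vessel mask after
    dilating both by ``dilation_px`` voxels (cubic structuring element)."""
    if objects.labels.shape != vessels.mask.shape:
        raise GridMismatchError("objects and vessels are on different grids")
    if dilation_px < 0:
        raise ValueError("dilation_px must be >= 0")
    vx, vy, vz = objects.voxel_size
    voxvol = vx * vy * vz
    size = 2 * dilation_px + 1
    struct = np.ones((size, size, size), bool)
    vessels_dil = (
        ndi.binary_dilation(vessels.mask, structure=struct)
        if dilation_px
        else vessels.mask.astype(bool)
    )
    records = []
    slices = ndi.find_objects(objects.labels)
    for oid in objects.ids:
        sl = slices[oid - 1]
        pad = tuple(
            slice(max(s.start - dilation_px, 0), min(s.stop + dilation_px, dim))
            for s, dim in zip(sl, objects.labels.shape)
        )
        obj = objects.labels[pad] == oid
        if dilation_px:
            obj = ndi.binary_dilation(obj, structure=struct)
        overlap = int(np.count_nonzero(obj & vessels_dil[pad]))
        records.append(ProximityRecord(object_id=int(oid), overlap_volume_um3=overlap * voxvol))
    return records


def _surface_vertices(
    mask: np.ndarray, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Marching-cubes surface vertices in physical (z, y, x) µm, with the
    grid anisotropy applied before extraction."""
    vx, vy, vz = voxel_size
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, *_ = marching_cubes(padded, level=0.5, spacing=(vz, vy, vx))
    return verts - np.array([vz, vy, vx])


def surface_distance(
    objects: ObjectLabels3D,
    vessels: VesselMask3D,
) -> tuple[list[ProximityRecord], float]:
    """Shortest surface-to-surface distance (µm) from each object to the
    vessel network: marching-cubes surfaces, nearest neighbour via a k-d
    tree. Returns per-object records and their mean (the per-ROI summary)."""
    if objects.labels.shape != vessels.mask.shape:
        raise GridMismatchError("objects and vessels are on different grids")
    if not vessels.mask.any():
        raise NoVesselError("empty vessel mask")
    vverts = _surface_vertices(vessels.mask, vessels.voxel_size)
    tree = cKDTree(vverts)
    records = []
    for oid in objects.ids:
        overts = _surface_vertices(objects.labels == oid, objects.voxel_size)
        if len(overts) == 0:
            raise ValueError(f"object {oid} has an empty surface")
        dmin = float(tree.query(overts, k=1)[0].min())
        records.append(ProximityRecord(object_id=int(oid), surface_distance_um=dmin))
    mean = float(np.mean([r.surface_distance_um for r in records])) if records else math.nan
    return records, mean
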