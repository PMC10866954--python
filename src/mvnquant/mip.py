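"""High-content-screening-style 2D quantification of maximum intensity
projections: marker region masks by fractional thresholding, nuclei
segmentation, border-based nucleus-to-region assignment, pericyte coverage,
the ghost-vessel fraction, and apoptosis co-localization.

All images entering the threshold operations are normalized to [0, 1] by
clipping at a fixed intensity ceiling; thresholds are fractions of that
clipped range. Physical borders (µm) are converted to pixels by rounding up
and applied as Euclidean-disk dilations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from ._geom import dilate_um
from .errors import (
    GridMismatchError,
    UndefinedFractionError,
    UndefinedViabilityError,
    UnknownMarkerError,
)

# Fractional thresholds of the clipped [0, 1] range per marker region.
REGION_THRESHOLDS = {"EC": 0.25, "pericyte": 0.40, "astrocyte": 0.40, "ECM": 0.40}
# The ECM channel gets a heavier median smoothing (radius in px) before
# thresholding; all other channels use the common 3 px median upstream.
ECM_MEDIAN_RADIUS_PX = 10
COMMON_MEDIAN_RADIUS_PX = 3
DEFAULT_CLIP_MAX = 20000.0

# Outer borders (µm) used to assign nuclei to marker regions.
ASSIGNMENT_BORDERS_UM = {"EC": 3.0, "pericyte": 2.0, "astrocyte": 2.0, "ECM": 3.0}
COVERAGE_BORDER_UM = 5.0

# Mapping from stack channel roles to region marker labels.
ROLE_TO_MARKER = {"endothelium": "EC", "pericyte": "pericyte", "astrocyte": "astrocyte", "colIV": "ECM"}


@dataclass
class RegionMaskSet:
    """Binary marker masks on a common 2D grid with physical calibration."""

    masks: dict[str, np.ndarray]
    pixel_size: tuple[float, float]
    source_thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise GridMismatchError(f"region masks differ in shape: {shapes}")

    @property
    def pixel_area(self) -> float:
        return self.pixel_size[0] * self.pixel_size[1]

    def area_um2(self, marker: str) -> float:
        return float(np.count_nonzero(self.masks[marker])) * self.pixel_area


@dataclass
class NucleiLabels:
    """Labeled nuclei with per-object morphology and apoptosis flags."""

    labels: np.ndarray
    pixel_size: tuple[float, float]
    table: pd.DataFrame  # id, area_um2, centroid_y, centroid_x, apoptotic

    @property
    def count(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()


@dataclass
class RoiMetrics:
    """Derived per-ROI quantities (areas in µm²)."""

    vascular_area: float
    pericyte_area: float
    astrocyte_area: float
    ecm_area: float
    coverage_area: float
    ghost_fraction: float
    nuclei_counts: dict[str, int]
    nuclei_total: int
    apoptotic_counts: dict[str, int]
    apoptotic_total: int
    viability: float

    def as_dict(self) -> dict[str, float]:
        out = {
            "vascular_area": self.vascular_area,
            "pericyte_area": self.pericyte_area,
            "astrocyte_area": self.astrocyte_area,
            "ecm_area": self.ecm_area,
            "coverage_area": self.coverage_area,
            "ghost_fraction": self.ghost_fraction,
            "nuclei_total": self.nuclei_total,
            "apoptotic_total": self.apoptotic_total,
            "viability": self.viability,
        }
        for m, c in self.nuclei_counts.items():
            out[f"nuclei_{m}"] = c
        for m, c in self.apoptotic_counts.items():
            out[f"apoptotic_{m}"] = c
        return out


def normalize_and_smooth(
    image: np.ndarray,
    clip_max: float = DEFAULT_CLIP_MAX,
    median_radius: int = COMMON_MEDIAN_RADIUS_PX,
) -> np.ndarray:
    """Clip to [0, clip_max], scale to [0, 1], median-filter with a square
    window of side 2·radius + 1. Radius 0 skips filtering."""
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    if clip_max <= 0:
        raise ValueError("clip_max must be > 0")
    if median_radius < 0:
        raise ValueError("median_radius must be >= 0")
    out = np.clip(image, 0.0, clip_max) / clip_max
    if median_radius > 0:
        out = ndi.median_filter(out, size=2 * median_radius + 1, mode="nearest")
    return out


def threshold_region(
    image01: np.ndarray,
    marker: str,
    thresholds: dict[str, float] | None = None,
) -> np.ndarray:
    """Binary marker region: image ≥ marker threshold. The ECM marker gets
    its additional 10 px median smoothing inside this operation."""
    thr_map = REGION_THRESHOLDS if thresholds is None else thresholds
    if marker not in thr_map:
        raise UnknownMarkerError(f"no threshold registered for marker {marker!r}")
    img = np.asarray(image01, dtype=float)
    if marker == "ECM":
        img = ndi.median_filter(img, size=2 * ECM_MEDIAN_RADIUS_PX + 1, mode="nearest")
    return img >= thr_map[marker]


def build_region_masks(
    images01: dict[str, np.ndarray],
    pixel_size: tuple[float, float],
    thresholds: dict[str, float] | None = None,
) -> RegionMaskSet:
    """Threshold a dict of normalized marker images into a RegionMaskSet."""
    thr_map = REGION_THRESHOLDS if thresholds is None else thresholds
    masks = {m: threshold_region(img, m, thr_map) for m, img in images01.items()}
    used = {m: thr_map[m] for m in masks}
    return RegionMaskSet(masks=masks, pixel_size=pixel_size, source_thresholds=used)


def segment_nuclei(
    dapi01: np.ndarray,
    pixel_size: tuple[float, float],
    min_area_um2: float = 20.0,
    *,
    smoothing_sigma_px: float = 2.0,
    peak_min_distance_px: int = 3,
) -> NucleiLabels:
    """Segment nuclei from a normalized DAPI projection.

    Pipeline: Gaussian smoothing → global Otsu → hole filling →
    distance-transform watershed split → remove objects below the area
    floor. A blank image yields an empty label set.
    """
    img = ndi.gaussian_filter(np.asarray(dapi01, dtype=float), smoothing_sigma_px)
    if img.max() - img.min() < 1e-9:
        return _empty_nuclei(dapi01.shape, pixel_size)
    thr = threshold_otsu(img)
    fg = ndi.binary_fill_holes(img > thr)
    if not fg.any():
        return _empty_nuclei(dapi01.shape, pixel_size)
    dist = ndi.distance_transform_edt(fg)
    markers = _watershed_markers(dist, fg, peak_min_distance_px)
    labels = watershed(-dist, markers, mask=fg)

    px_area = pixel_size[0] * pixel_size[1]
    rows = []
    keep = np.zeros(labels.max() + 1, np.int32)
    next_id = 1
    for prop in regionprops(labels):
        area = prop.area * px_area
        if area < min_area_um2:
            continue
        keep[prop.label] = next_id
        rows.append(
            {
                "id": next_id,
                "area_um2": area,
                "centroid_y": prop.centroid[0],
                "centroid_x": prop.centroid[1],
                "apoptotic": False,
            }
        )
        next_id += 1
    relabeled = keep[labels]
    table = pd.DataFrame(rows, columns=["id", "area_um2", "centroid_y", "centroid_x", "apoptotic"])
    return NucleiLabels(labels=relabeled, pixel_size=pixel_size, table=table)


def _empty_nuclei(shape, pixel_size) -> NucleiLabels:
    return NucleiLabels(
        labels=np.zeros(shape, np.int32),
        pixel_size=pixel_size,
        table=pd.DataFrame(columns=["id", "area_um2", "centroid_y", "centroid_x", "apoptotic"]),
    )


def _watershed_markers(dist: np.ndarray, fg: np.ndarray, min_distance: int) -> np.ndarray:
    """Watershed seeds: local maxima of the distance transform with a minimum
    separation; a flat plateau forms one connected peak region and hence one
    marker. Deterministic."""
    size = 2 * min_distance + 1
    peaks = fg & (dist >= ndi.maximum_filter(dist, size=size))
    markers, _ = ndi.label(peaks)
    return markers


def flag_apoptotic(
    nuclei: NucleiLabels, apoptosis01: np.ndarray, threshold: float = 0.25
) -> NucleiLabels:
    """Set per-nucleus apoptotic flags where the mean apoptosis-reporter
    intensity inside the nucleus exceeds the threshold."""
    if apoptosis01.shape != nuclei.labels.shape:
        raise GridMismatchError("apoptosis image and nuclei labels differ in shape")
    if nuclei.count == 0:
        return nuclei
    means = ndi.labeled_comprehension(
        apoptosis01, nuclei.labels, nuclei.ids, np.mean, float, 0.0
    )
    nuclei.table["apoptotic"] = means > threshold
    return nuclei


def _border_masks(
    regions: RegionMaskSet, borders_um: dict[str, float] | None = None
) -> dict[str, np.ndarray]:
    borders = ASSIGNMENT_BORDERS_UM if borders_um is None else borders_um
    return {
        m: dilate_um(regions.masks[m], borders.get(m, 0.0), regions.pixel_size)
        for m in regions.masks
    }


def assign_nuclei_to_regions(
    nuclei: NucleiLabels,
    regions: RegionMaskSet,
    borders_um: dict[str, float] | None = None,
) -> dict[str, int]:
    """Count nuclei per marker: a nucleus counts for marker m when its mask
    intersects the m region dilated by the marker's outer border. Assignment
    is non-exclusive — one nucleus may count for several markers."""
    if nuclei.labels.shape != next(iter(regions.masks.values())).shape:
        raise GridMismatchError("nuclei labels and region masks differ in shape")
    membership = nuclei_region_membership(nuclei, regions, borders_um)
    return {m: int(membership[m].sum()) for m in membership.columns}


def nuclei_region_membership(
    nuclei: NucleiLabels,
    regions: RegionMaskSet,
    borders_um: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-nucleus boolean membership table (rows aligned with nuclei.table)."""
    dilated = _border_masks(regions, borders_um)
    out = {}
    for m, dmask in dilated.items():
        if nuclei.count == 0:
            out[m] = np.zeros(0, bool)
            continue
        hit = np.zeros(nuclei.count, bool)
        overlap_labels = np.unique(nuclei.labels[dmask & (nuclei.labels > 0)])
        id_to_row = {i: k for k, i in enumerate(nuclei.ids)}
        for lab in overlap_labels:
            if lab in id_to_row:
                hit[id_to_row[lab]] = True
        out[m] = hit
    return pd.DataFrame(out, index=nuclei.table.index)


def pericyte_coverage(
    regions: RegionMaskSet, border_um: float = COVERAGE_BORDER_UM
) -> float:
    """Pericyte coverage area (µm²): pericyte region ∩ EC region dilated by
    the coverage border."""
    for m in ("EC", "pericyte"):
        if m not in regions.masks:
            raise UnknownMarkerError(f"region mask {m!r} required for coverage")
    dil = dilate_um(regions.masks["EC"], border_um, regions.pixel_size)
    return float(np.count_nonzero(regions.masks["pericyte"] & dil)) * regions.pixel_area


def ghost_vessel_fraction(regions: RegionMaskSet) -> float:
    """Fraction of ghost vessels: avascular ECM area / ECM area,
    i.e. area(ECM \\ EC) / area(ECM), clamped to [0, 1]."""
    for m in ("EC", "ECM"):
        if m not in regions.masks:
            raise UnknownMarkerError(f"region mask {m!r} required for ghost fraction")
    ecm = regions.masks["ECM"]
    n_ecm = int(np.count_nonzero(ecm))
    if n_ecm == 0:
        raise UndefinedFractionError("ghost-vessel fraction undefined: empty ECM mask")
    avascular = np.count_nonzero(ecm & ~regions.masks["EC"].astype(bool))
    return float(min(max(avascular / n_ecm, 0.0), 1.0))


def apoptosis_colocalization(
    nuclei: NucleiLabels,
    regions: RegionMaskSet,
    borders_um: dict[str, float] | None = None,
) -> tuple[dict[str, int], float]:
    """Apoptotic-nucleus counts per marker (same border rule as nucleus
    assignment) and overall viability = 1 − apoptotic / total nuclei."""
    if nuclei.count == 0:
        raise UndefinedViabilityError("viability undefined with zero nuclei")
    membership = nuclei_region_membership(nuclei, regions, borders_um)
    apo = nuclei.table["apoptotic"].to_numpy(dtype=bool)
    counts = {m: int((membership[m].to_numpy() & apo).sum()) for m in membership.columns}
    viability = 1.0 - apo.sum() / nuclei.count
    return counts, viability


def quantify_roi(
    images01: dict[str, np.ndarray],
    pixel_size: tuple[float, float],
    dapi01: np.ndarray | None = None,
    apoptosis01: np.ndarray | None = None,
    *,
    thresholds: dict[str, float] | None = None,
    min_nucleus_area_um2: float = 20.0,
) -> RoiMetrics:
    """Full MIP quantification of one ROI.

    images01: normalized marker images keyed by region marker
    ("EC", "pericyte", "astrocyte", "ECM"); missing markers yield zero areas
    and an undefined (NaN) ghost fraction when ECM is absent.
    """
    regions = build_region_masks(images01, pixel_size, thresholds)

    def area(m: str) -> float:
        return regions.area_um2(m) if m in regions.masks else 0.0

    coverage = (
        pericyte_coverage(regions)
        if "EC" in regions.masks and "pericyte" in regions.masks
        else 0.0
    )
    if "ECM" in regions.masks and "EC" in regions.masks and regions.masks["ECM"].any():
        ghost = ghost_vessel_fraction(regions)
    else:
        ghost = math.nan

    if dapi01 is not None:
        nuclei = segment_nuclei(dapi01, pixel_size, min_nucleus_area_um2)
        if apoptosis01 is not None:
            nuclei = flag_apoptotic(nuclei, apoptosis01)
        counts = assign_nuclei_to_regions(nuclei, regions)
        if nuclei.count > 0:
            apo_counts, viability = apoptosis_colocalization(nuclei, regions)
        else:
            apo_counts = {m: 0 for m in regions.masks}
            viability = math.nan
        total = nuclei.count
        apo_total = int(nuclei.table["apoptotic"].sum()) if total else 0
    else:
        counts = {m: 0 for m in regions.masks}
        apo_counts = {m: 0 for m in regions.masks}
        total = 0
        apo_total = 0
        viability = math.nan

    return RoiMetrics(
        vascular_area=area("EC"),
        pericyte_area=area("pericyte"),
        astrocyte_area=area("astrocyte"),
        ecm_area=area("ECM"),
        coverage_area=coverage,
        ghost_fraction=ghost,
        nuclei_counts=counts,
        nuclei_total=total,
        apoptotic_counts=apo_counts,
        apoptotic_total=apo_total,
        viability=viability,
    )
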