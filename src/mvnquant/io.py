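"""Reading, writing and basic reshaping of multi-channel image stacks.

Stacks are stored as plain multi-page TIFF with channel-major page order
(page index = c * Z + z) plus a YAML sidecar carrying the physical voxel
size, the channel-role map and free-text provenance. OME-TIFF voxel-size
metadata is honoured when present; a stack without any calibration is an
error, never a silent default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import CalibrationMissingError, GridMismatchError, LayoutInvalidError


@dataclass
class ChannelStack:
    """Multi-channel 3D voxel grid with physical calibration.

    data: (C, Z, Y, X) array; voxel_size: (x, y, z) µm;
    channel_roles: role label → channel index.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_roles: dict[str, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be (C, Z, Y, X), got shape {self.data.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        c = self.data.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < c:
                raise ValueError(f"role {role!r} maps to channel {idx}, but stack has {c}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def pixel_size(self) -> tuple[float, float]:
        return (self.voxel_size[0], self.voxel_size[1])

    def channel(self, role: str) -> np.ndarray:
        """Return the (Z, Y, X) array for a mapped role."""
        if role not in self.channel_roles:
            raise KeyError(f"role {role!r} is not mapped; have {sorted(self.channel_roles)}")
        return self.data[self.channel_roles[role]]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(stack: ChannelStack, path: str | Path) -> Path:
    """Write a ChannelStack as channel-major multi-page TIFF + YAML sidecar."""
    path = Path(path)
    c, z, y, x = stack.data.shape
    pages = stack.data.reshape(c * z, y, x)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "voxel_size_um": [float(v) for v in stack.voxel_size],
        "channels": {str(k): int(v) for k, v in stack.channel_roles.items()},
        "shape_czyx": [int(c), int(z), int(y), int(x)],
        "provenance": stack.provenance,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def _ome_voxel_size(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    try:
        if not tif.is_ome or tif.ome_metadata is None:
            return None
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        for el in root.iter():
            if el.tag.endswith("Pixels"):
                px = el.get("PhysicalSizeX")
                py = el.get("PhysicalSizeY")
                pz = el.get("PhysicalSizeZ")
                if px and py and pz:
                    return (float(px), float(py), float(pz))
    except Exception:
        return None
    return None


def read_stack(path: str | Path, channel_roles: dict[str, int] | None = None) -> ChannelStack:
    """Read a multi-page TIFF into a ChannelStack.

    The voxel size and channel map come from the YAML sidecar when present,
    else from OME metadata (roles must then be supplied). Missing calibration
    raises CalibrationMissingError.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        ome_vs = _ome_voxel_size(tif)
    if pages.ndim == 2:
        pages = pages[None]

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        voxel_size = tuple(float(v) for v in meta["voxel_size_um"])
        roles = {str(k): int(v) for k, v in meta.get("channels", {}).items()}
        c, z, y, x = meta["shape_czyx"]
        if pages.shape[0] != c * z or pages.shape[1:] != (y, x):
            raise ValueError(
                f"TIFF pages {pages.shape} inconsistent with sidecar shape {(c, z, y, x)}"
            )
        data = pages.reshape(c, z, y, x)
        if channel_roles:
            roles = dict(channel_roles)
        return ChannelStack(data, voxel_size, roles, meta.get("provenance") or {})

    if ome_vs is not None:
        if channel_roles is None:
            raise CalibrationMissingError(
                f"{path}: OME voxel size found but no channel-role map supplied"
            )
        c = max(channel_roles.values()) + 1
        if pages.shape[0] % c:
            raise ValueError(f"page count {pages.shape[0]} not divisible by {c} channels")
        z = pages.shape[0] // c
        data = pages.reshape(c, z, *pages.shape[1:])
        return ChannelStack(data, ome_vs, dict(channel_roles), {"source": str(path)})

    raise CalibrationMissingError(
        f"{path}: no voxel-size calibration (no YAML sidecar, no OME metadata)"
    )


def max_projection(stack: ChannelStack, role: str) -> tuple[np.ndarray, tuple[float, float]]:
    """Maximum intensity projection over Z for one channel role.

    Returns (2D image, (x, y) pixel size µm).
    """
    chan = stack.channel(role)
    return chan.max(axis=0), stack.pixel_size


@dataclass(frozen=True)
class RoiLayout:
    """Non-overlapping half-open rectangles (x0, y0, x1, y1) in pixels."""

    roi_bounds: tuple[tuple[int, int, int, int], ...]

    def validate(self, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        occupancy = np.zeros(image_shape, dtype=np.uint8)
        for x0, y0, x1, y1 in self.roi_bounds:
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise LayoutInvalidError(
                    f"rectangle {(x0, y0, x1, y1)} outside image bounds {(w, h)}"
                )
            occupancy[y0:y1, x0:x1] += 1
        if occupancy.max(initial=0) > 1:
            raise LayoutInvalidError("ROI rectangles overlap")


def default_layout(image_shape: tuple[int, int], n_rois: int) -> RoiLayout:
    """Equal partition along the image's long axis into n_rois tiles (n ≤ 15)."""
    if not 1 <= n_rois <= 15:
        raise LayoutInvalidError(f"roi count must be in [1, 15], got {n_rois}")
    h, w = image_shape
    bounds = []
    if w >= h:
        edges = np.linspace(0, w, n_rois + 1).round().astype(int)
        for a, b in zip(edges[:-1], edges[1:]):
            bounds.append((int(a), 0, int(b), h))
    else:
        edges = np.linspace(0, h, n_rois + 1).round().astype(int)
        for a, b in zip(edges[:-1], edges[1:]):
            bounds.append((0, int(a), w, int(b)))
    return RoiLayout(tuple(bounds))


def tile_rois(image: np.ndarray, layout: RoiLayout) -> list[np.ndarray]:
    """Crop an image into the layout's ROIs, in layout order."""
    if image.ndim != 2:
        raise GridMismatchError(f"expected a 2D image, got shape {image.shape}")
    layout.validate(image.shape)
    return [image[y0:y1, x0:x1] for x0, y0, x1, y1 in layout.roi_bounds]
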