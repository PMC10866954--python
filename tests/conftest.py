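"""Shared fixtures: a desk-scale grid and cached synthetic scenes.

Scenes are expensive, so condition sets used by several tests are built once
per session. The small grid keeps the full suite fast while preserving the
default anisotropic voxel calibration.
"""

from __future__ import annotations

import numpy as np
import pytest

from mvnquant import GridSpec, NOISE_OFF, generate_scene
from mvnquant.io import max_projection
from mvnquant.mip import ROLE_TO_MARKER, build_region_masks, normalize_and_smooth

SMALL_GRID = GridSpec(shape=(24, 128, 256), voxel_size=(0.6, 0.6, 5.0))
RECOVERY_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return SMALL_GRID


@pytest.fixture(scope="session")
def scene_control_noisefree():
    return generate_scene("control_D7", 3, grid=SMALL_GRID, noise=NOISE_OFF)


@pytest.fixture(scope="session")
def scene_control_noisy():
    return generate_scene("control_D7", 3, grid=SMALL_GRID)


def mip_pipeline_metrics(scene) -> dict[str, float]:
    """Run the full MIP quantification chain (projection, normalization,
    thresholding, region metrics) on a scene and return the headline
    morphology metrics."""
    from mvnquant.mip import ghost_vessel_fraction, pericyte_coverage

    images01 = {}
    px = scene.grid.pixel_size
    for role in ("endothelium", "pericyte", "astrocyte", "colIV"):
        img, px = max_projection(scene.stack, role)
        images01[ROLE_TO_MARKER[role]] = normalize_and_smooth(img, clip_max=1.0)
    regions = build_region_masks(images01, px)
    vascular = regions.area_um2("EC")
    coverage = pericyte_coverage(regions)
    return {
        "vascular_area": vascular,
        "pericyte_area": regions.area_um2("pericyte"),
        "coverage_area": coverage,
        "coverage_fraction": coverage / vascular if vascular else np.nan,
        "ghost_fraction": ghost_vessel_fraction(regions),
    }


@pytest.fixture(scope="session")
def recovery_metrics():
    """Pipeline-measured MIP metrics for the four recovery conditions,
    5 seeds each, default noise, on the desk-scale grid."""
    out: dict[str, list[dict[str, float]]] = {}
    for preset in ("control_D7", "control_D14", "control_D28", "diabetic_D28"):
        rows = []
        for seed in RECOVERY_SEEDS:
            scene = generate_scene(preset, seed, grid=SMALL_GRID)
            rows.append(mip_pipeline_metrics(scene))
        out[preset] = rows
    return out


def mean_metric(rows: list[dict[str, float]], key: str) -> float:
    return float(np.mean([r[key] for r in rows]))
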