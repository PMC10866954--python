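"""3D segmentation, classifier refinement and proximity metrics."""

import numpy as np
import pytest

from mvnquant.errors import DegenerateHistogramError, GridMismatchError, NoVesselError
from mvnquant.volume import (
    ObjectLabels3D,
    _surface_vertices,
    _vessel_mask_with_geometry,
    apply_pixel_classifier,
    denoise_stack,
    proximity_overlap,
    segment_objects_3class,
    segment_vasculature_random_walk,
    surface_distance,
    train_pixel_classifier,
)

ISO = (1.0, 1.0, 1.0)


def make_sphere(shape, center, radius):
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius**2


class TestDenoise:
    def test_flat_background_removed(self):
        img = np.full((3, 64, 64), 100.0)
        out = denoise_stack(img, gaussian_sigma=0, ball_radius=10)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_blob_contrast_preserved_on_ramp(self):
        """A compact bright blob on a linear ramp keeps its contrast while the
        ramp is removed; oracle = grey-opening background estimate."""
        from scipy import ndimage as ndi

        ramp = np.linspace(0, 0.2, 96)[None, None, :] * np.ones((1, 64, 96))
        img = ramp.copy()
        yy, xx = np.mgrid[:64, :96]
        blob = ((yy - 32) ** 2 + (xx - 48) ** 2) <= 36
        img[0][blob] += 0.5
        out = denoise_stack(img, gaussian_sigma=0, ball_radius=30)
        opened = ndi.grey_opening(img[0], size=(61, 61))
        oracle = img[0] - opened
        blob_contrast = out[0][blob].mean()
        assert blob_contrast == pytest.approx(oracle[blob].mean(), rel=0.10)
        far = out[0][~ndi.binary_dilation(blob, iterations=20)]
        assert far.mean() < 0.05 * 0.5

    def test_nonfinite_rejected(self):
        img = np.zeros((2, 8, 8))
        img[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            denoise_stack(img)


class TestThreeClassSegmentation:
    def test_only_top_class_is_foreground(self):
        img = np.full((6, 48, 48), 0.1)
        img[1:4, 5:15, 5:15] = 0.5    # mid class
        img[1:4, 30:40, 30:40] = 0.9  # top class
        objs = segment_objects_3class(img, "pericyte", ISO, min_volume_um3=10)
        assert objs.count == 1
        zz, yy, xx = np.nonzero(objs.labels)
        assert yy.min() >= 28 and xx.min() >= 28

    def test_fused_spheres_split(self):
        # two bright spheres touching at a thin neck, plus a mid-intensity
        # blob so the histogram is genuinely trimodal (it must NOT be labeled)
        vol = np.full((24, 40, 64), 0.05)
        vol[make_sphere(vol.shape, (12, 20, 22), 9)] = 0.9
        vol[make_sphere(vol.shape, (12, 20, 40), 9)] = 0.9
        vol[make_sphere(vol.shape, (5, 8, 55), 4)] = 0.45
        objs = segment_objects_3class(vol, "pericyte", ISO, min_volume_um3=10)
        assert objs.count == 2
        assert not (objs.labels[:, :, 50:] > 0).any()

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            segment_objects_3class(np.full((4, 8, 8), 0.5), "pericyte", ISO)

    def test_counts_match_generator_truth(self, scene_control_noisefree):
        """Per-marker object counts on a noise-free scene equal the
        generator's cell-body counts exactly."""
        scene = scene_control_noisefree
        vs = scene.grid.voxel_size
        tt = scene.truth.nuclei_table
        for role, ctype in (("pericyte", "pericyte"), ("astrocyte", "astrocyte")):
            chan = np.asarray(scene.stack.channel(role))
            objs = segment_objects_3class(denoise_stack(chan), role, vs)
            assert objs.count == int((tt.cell_type == ctype).sum()), role


class TestRandomWalkVasculature:
    def test_synthetic_tube_dice(self, scene_control_noisefree):
        scene = scene_control_noisefree
        den = denoise_stack(np.asarray(scene.stack.channel("endothelium")))
        vessels = segment_vasculature_random_walk(den, scene.grid.voxel_size)
        truth = scene.truth.vessel_mask
        dice = 2 * (vessels.mask & truth).sum() / (vessels.mask.sum() + truth.sum())
        assert dice >= 0.95
        assert (vessels.mask & vessels.skeleton).sum() == vessels.skeleton.sum()

    def test_cylinder_diameter(self):
        r = 6.0
        vol = np.zeros((20, 20, 60))
        zz, yy, _ = np.mgrid[:20, :20, :60]
        vol[((zz - 10) ** 2 + (yy - 10) ** 2) <= r**2] = 0.9
        vol += 0.02
        vol[0, 0, 0:3] = 0.45  # trimodal histogram helper
        vessels = segment_vasculature_random_walk(vol, ISO)
        assert vessels.mean_diameter_um == pytest.approx(2 * r, rel=0.10)

    def test_all_above_upper_cut_limit(self):
        img = np.full((4, 16, 16), 0.9)
        img[0, :2, :2] = 0.0
        img[0, 2:4, :2] = 0.45
        vessels = segment_vasculature_random_walk(img, ISO)
        # nearly everything seeds as vessel; mask covers the bright plateau
        assert vessels.mask[1:].all()


class TestPixelClassifier:
    def _toy(self, seed):
        rng = np.random.default_rng(seed)
        img = np.zeros((6, 32, 32), np.float32)
        img[2:5, 8:24, 8:24] = 0.8
        img += rng.normal(0, 0.02, img.shape).astype(np.float32)
        return img, np.zeros(img.shape, bool) | (np.arange(img.shape[0])[:, None, None] >= 2) & (
            np.arange(img.shape[0])[:, None, None] < 5
        ) & np.pad(np.ones((16, 16), bool), 8)[None]

    def test_memorization_bound(self):
        img, mask = self._toy(0)
        clf = train_pixel_classifier([img], [mask], seed=1, n_estimators=25, n_samples_per_stack=8000)
        pred = apply_pixel_classifier(clf, img)
        dice = 2 * (pred & mask).sum() / (pred.sum() + mask.sum())
        assert dice >= 0.99

    def test_generalizes_to_unseen_stack(self):
        train = [self._toy(s) for s in (0, 1)]
        clf = train_pixel_classifier(
            [i for i, _ in train], [m for _, m in train], seed=2, n_estimators=25,
            n_samples_per_stack=8000,
        )
        img, mask = self._toy(7)
        pred = apply_pixel_classifier(clf, img)
        dice = 2 * (pred & mask).sum() / (pred.sum() + mask.sum())
        assert dice >= 0.90

    def test_seeded_determinism(self):
        img, mask = self._toy(0)
        p1 = apply_pixel_classifier(
            train_pixel_classifier([img], [mask], seed=5, n_estimators=10, n_samples_per_stack=4000), img
        )
        p2 = apply_pixel_classifier(
            train_pixel_classifier([img], [mask], seed=5, n_estimators=10, n_samples_per_stack=4000), img
        )
        assert np.array_equal(p1, p2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            train_pixel_classifier([np.zeros((2, 4, 4))], [np.zeros((2, 4, 5), bool)], seed=0)


class TestProximity:
    def _pair(self, gap):
        vol = np.zeros((12, 12, 40), bool)
        vol[4:8, 4:8, 2:6] = True
        obj = np.zeros_like(vol, np.int32)
        x0 = 6 + gap
        obj[4:8, 4:8, x0 : x0 + 4] = 1
        vessels = _vessel_mask_with_geometry(vol, ISO)
        return ObjectLabels3D(obj, ISO, "pericyte"), vessels

    def test_far_object_no_overlap(self):
        objs, vessels = self._pair(gap=10)
        recs = proximity_overlap(objs, vessels, dilation_px=3)
        assert recs[0].overlap_volume_um3 == 0.0

    def test_abutting_object_overlaps(self):
        objs, vessels = self._pair(gap=0)
        recs = proximity_overlap(objs, vessels, dilation_px=3)
        assert recs[0].overlap_volume_um3 > 0

    def test_object_inside_vessel_contains_own_volume(self):
        vol = np.zeros((10, 10, 10), bool)
        vol[2:8, 2:8, 2:8] = True
        obj = np.zeros_like(vol, np.int32)
        obj[4:6, 4:6, 4:6] = 1
        vessels = _vessel_mask_with_geometry(vol, ISO)
        recs = proximity_overlap(ObjectLabels3D(obj, ISO, "x"), vessels, dilation_px=3)
        assert recs[0].overlap_volume_um3 >= 8.0

    def test_bruteforce_dilation_oracle(self):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(2)
        vol = rng.random((12, 12, 12)) < 0.1
        if not vol.any():
            vol[0, 0, 0] = True
        obj = np.zeros(vol.shape, np.int32)
        obj[6:9, 6:9, 6:9] = 1
        vessels = _vessel_mask_with_geometry(vol, ISO)
        recs = proximity_overlap(ObjectLabels3D(obj, ISO, "x"), vessels, dilation_px=2)
        struct = np.ones((5, 5, 5), bool)
        oracle = (
            ndi.binary_dilation(obj == 1, structure=struct)
            & ndi.binary_dilation(vol, structure=struct)
        ).sum()
        assert recs[0].overlap_volume_um3 == pytest.approx(float(oracle))

    def test_dilation_monotonicity(self):
        objs, vessels = self._pair(gap=4)
        vols = [
            proximity_overlap(objs, vessels, dilation_px=d)[0].overlap_volume_um3
            for d in range(0, 5)
        ]
        assert all(b >= a for a, b in zip(vols, vols[1:]))

    def test_overlap_implies_bounded_surface_distance(self):
        objs, vessels = self._pair(gap=4)
        d = 3
        rec = proximity_overlap(objs, vessels, dilation_px=d)[0]
        dist = surface_distance(objs, vessels)[0][0].surface_distance_um
        if rec.overlap_volume_um3 > 0:
            assert dist <= 2 * d * max(ISO)


class TestSurfaceDistance:
    def test_face_gap_between_cubes(self):
        vol = np.zeros((12, 12, 30), bool)
        vol[4:8, 4:8, 2:6] = True
        obj = np.zeros_like(vol, np.int32)
        obj[4:8, 4:8, 10:14] = 1
        vessels = _vessel_mask_with_geometry(vol, ISO)
        recs, mean = surface_distance(ObjectLabels3D(obj, ISO, "x"), vessels)
        half_diag = np.linalg.norm(ISO) / 2
        assert abs(recs[0].surface_distance_um - 4.0) <= half_diag
        assert mean == recs[0].surface_distance_um

    def test_touching_is_zero(self):
        vol = np.zeros((10, 10, 20), bool)
        vol[3:7, 3:7, 2:8] = True
        obj = np.zeros_like(vol, np.int32)
        obj[3:7, 3:7, 8:12] = 1
        vessels = _vessel_mask_with_geometry(vol, ISO)
        recs, _ = surface_distance(ObjectLabels3D(obj, ISO, "x"), vessels)
        assert recs[0].surface_distance_um <= np.linalg.norm(ISO) / 2

    def test_tree_matches_exhaustive_pairwise(self):
        vol = np.zeros((14, 14, 14), bool)
        vol[2:6, 2:6, 2:6] = True
        obj = np.zeros_like(vol, np.int32)
        obj[8:12, 7:12, 6:13] = 1
        vessels = _vessel_mask_with_geometry(vol, (0.6, 0.6, 5.0))
        objs = ObjectLabels3D(obj, (0.6, 0.6, 5.0), "x")
        recs, _ = surface_distance(objs, vessels)
        va = _surface_vertices(vol, (0.6, 0.6, 5.0))
        vb = _surface_vertices(obj == 1, (0.6, 0.6, 5.0))
        assert len(va) <= 500 or len(vb) <= 500
        brute = min(float(np.linalg.norm(a - b)) for a in va for b in vb)
        assert recs[0].surface_distance_um == pytest.approx(brute)

    def test_empty_vessel_mask_errors(self):
        obj = np.zeros((4, 4, 4), np.int32)
        obj[1:3, 1:3, 1:3] = 1
        with pytest.raises(NoVesselError):
            _vessel_mask_with_geometry(np.zeros((4, 4, 4), bool), ISO)
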