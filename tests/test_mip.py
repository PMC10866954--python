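"""MIP quantification: normalization, thresholds, nuclei, coverage, ghost
fraction, apoptosis — each against explicit brute-force pixel oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mvnquant.errors import (
    UndefinedFractionError,
    UndefinedViabilityError,
    UnknownMarkerError,
)
from mvnquant.mip import (
    NucleiLabels,
    RegionMaskSet,
    apoptosis_colocalization,
    assign_nuclei_to_regions,
    flag_apoptotic,
    ghost_vessel_fraction,
    normalize_and_smooth,
    pericyte_coverage,
    segment_nuclei,
    threshold_region,
)

# ---------------------------------------------------------------------------
# Brute-force pixel oracles (kept independent of the implementation path)
# ---------------------------------------------------------------------------


def brute_dilate(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """O(n^2) Euclidean-disk dilation by exhaustive pixel pairs."""
    out = np.zeros_like(mask, dtype=bool)
    fg = np.argwhere(mask)
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            for fy, fx in fg:
                if (y - fy) ** 2 + (x - fx) ** 2 <= radius_px**2:
                    out[y, x] = True
                    break
    return out


def brute_coverage_area(peri, ec, border_px, px_area=1.0) -> float:
    return float(np.count_nonzero(peri & brute_dilate(ec, border_px))) * px_area


def brute_ghost_fraction(ecm, ec) -> float:
    return np.count_nonzero(ecm & ~ec) / np.count_nonzero(ecm)


def _labels_from_points(shape, points):
    lab = np.zeros(shape, np.int32)
    rows = []
    for k, (y, x) in enumerate(points, start=1):
        lab[y, x] = k
        rows.append({"id": k, "area_um2": 1.0, "centroid_y": y, "centroid_x": x, "apoptotic": False})
    return NucleiLabels(lab, (1.0, 1.0), pd.DataFrame(rows))


class TestNormalizeAndSmooth:
    def test_clipping_to_unit_range(self):
        img = np.full((5, 5), 40000.0)
        assert np.array_equal(normalize_and_smooth(img, 20000, 0), np.ones((5, 5)))

    def test_radius_zero_is_scaled_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 30000, (8, 8))
        out = normalize_and_smooth(img, 20000, 0)
        assert np.array_equal(out, np.clip(img, 0, 20000) / 20000)

    def test_median_suppresses_isolated_pixel(self):
        img = np.zeros((15, 15))
        img[7, 7] = 20000
        out = normalize_and_smooth(img, 20000, 3)
        assert out[7, 7] == 0.0

    def test_median_matches_windowed_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 20000, (11, 11))
        out = normalize_and_smooth(img, 20000, 1)
        # interior pixel: median of its 3x3 neighbourhood
        window = np.clip(img[4:7, 4:7], 0, 20000) / 20000
        assert out[5, 5] == pytest.approx(np.median(window))

    def test_nonfinite_rejected(self):
        img = np.zeros((4, 4))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            normalize_and_smooth(img, 20000, 0)


class TestThresholdRegion:
    def test_marker_thresholds(self):
        img = np.full((6, 6), 0.30)
        assert threshold_region(img, "EC").all()        # EC threshold 0.25
        assert not threshold_region(img, "pericyte").any()  # pericyte 0.40

    def test_checkerboard_any_marker(self):
        img = np.indices((8, 8)).sum(axis=0) % 2
        img = img.astype(float)
        for marker in ("EC", "pericyte", "astrocyte"):
            assert np.array_equal(threshold_region(img, marker), img.astype(bool))

    def test_unknown_marker(self):
        with pytest.raises(UnknownMarkerError):
            threshold_region(np.zeros((4, 4)), "neuron")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (8, 8), elements=st.floats(0, 1)))
    def test_lower_threshold_never_shrinks_mask(self, img):
        hi = threshold_region(img, "EC", {"EC": 0.4})
        lo = threshold_region(img, "EC", {"EC": 0.2})
        assert (lo | hi).sum() == lo.sum()  # hi ⊆ lo


class TestSegmentNuclei:
    def test_two_separated_blobs(self):
        img = np.zeros((60, 60))
        yy, xx = np.mgrid[:60, :60]
        img += 0.9 * np.exp(-(((yy - 15) ** 2 + (xx - 15) ** 2) / 30))
        img += 0.9 * np.exp(-(((yy - 45) ** 2 + (xx - 45) ** 2) / 30))
        nuc = segment_nuclei(img, (1.0, 1.0), min_area_um2=5)
        assert nuc.count == 2

    def test_touching_blobs_split_by_watershed(self):
        img = np.zeros((40, 70))
        yy, xx = np.mgrid[:40, :70]
        img[((yy - 20) ** 2 + (xx - 23) ** 2) <= 100] = 0.9
        img[((yy - 20) ** 2 + (xx - 44) ** 2) <= 100] = 0.9
        nuc = segment_nuclei(img, (1.0, 1.0), min_area_um2=5)
        assert nuc.count == 2

    def test_blank_image_empty_labels(self):
        nuc = segment_nuclei(np.zeros((30, 30)), (1.0, 1.0))
        assert nuc.count == 0 and not nuc.labels.any()

    def test_min_area_filter(self):
        img = np.zeros((40, 40))
        img[10:20, 10:20] = 0.9  # 100 px
        img[30:32, 30:32] = 0.9  # 4 px
        nuc = segment_nuclei(img, (1.0, 1.0), min_area_um2=20)
        assert nuc.count == 1


class TestAssignment:
    def _regions(self, shape=(40, 40)):
        ec = np.zeros(shape, bool)
        ec[10:20, 10:20] = True
        peri = np.zeros(shape, bool)
        peri[18:28, 18:28] = True
        return RegionMaskSet({"EC": ec, "pericyte": peri}, (1.0, 1.0))

    def test_border_inclusion_and_exclusion(self):
        regions = self._regions()
        # 2 µm outside the EC edge -> inside the 3 µm EC border
        near = _labels_from_points((40, 40), [(15, 22)])
        counts = assign_nuclei_to_regions(near, regions)
        assert counts["EC"] == 1
        # 10 µm away from everything -> counted nowhere
        far = _labels_from_points((40, 40), [(2, 37)])
        counts = assign_nuclei_to_regions(far, regions)
        assert counts["EC"] == 0 and counts["pericyte"] == 0

    def test_nonexclusive_membership_matches_bruteforce(self):
        regions = self._regions()
        nuc = _labels_from_points((40, 40), [(19, 19), (15, 24), (30, 23)])
        counts = assign_nuclei_to_regions(nuc, regions)
        borders = {"EC": 3, "pericyte": 2}
        expected = {m: 0 for m in borders}
        for m, b in borders.items():
            dil = brute_dilate(regions.masks[m], b)
            for _, row in nuc.table.iterrows():
                if dil[int(row.centroid_y), int(row.centroid_x)]:
                    expected[m] += 1
        assert counts == expected
        # the (19,19) nucleus sits in the overlap: counted for both markers
        from mvnquant.mip import nuclei_region_membership

        membership = nuclei_region_membership(nuc, regions)
        assert bool(membership.loc[0, "EC"]) and bool(membership.loc[0, "pericyte"])


class TestCoverage:
    def test_contained_pericytes_fully_counted(self):
        ec = np.zeros((30, 30), bool)
        ec[5:25, 5:25] = True
        peri = np.zeros((30, 30), bool)
        peri[10:20, 10:20] = True
        regions = RegionMaskSet({"EC": ec, "pericyte": peri}, (1.0, 1.0))
        assert pericyte_coverage(regions) == 100.0

    def test_ring_within_border_counted(self):
        ec = np.zeros((40, 40), bool)
        ec[15:25, 15:25] = True
        peri = np.zeros((40, 40), bool)
        peri[15:25, 28] = True  # 4 px outside the EC right edge
        regions = RegionMaskSet({"EC": ec, "pericyte": peri}, (1.0, 1.0))
        assert pericyte_coverage(regions) == 10.0  # full ring, 5 µm border

    def test_disjoint_beyond_border_zero(self):
        ec = np.zeros((40, 40), bool)
        ec[0:10, 0:10] = True
        peri = np.zeros((40, 40), bool)
        peri[0:10, 17:20] = True  # 7 px gap >= 6 µm
        regions = RegionMaskSet({"EC": ec, "pericyte": peri}, (1.0, 1.0))
        assert pericyte_coverage(regions) == 0.0

    def test_missing_mask(self):
        with pytest.raises(UnknownMarkerError):
            pericyte_coverage(RegionMaskSet({"EC": np.ones((4, 4), bool)}, (1.0, 1.0)))


class TestGhostFraction:
    def test_pixel_arithmetic(self):
        ecm = np.zeros((20, 20), bool)
        ecm[:10, :10] = True  # 100 px
        ec = np.zeros((20, 20), bool)
        ec[:10, :6] = True  # 60 px inside ECM
        regions = RegionMaskSet({"EC": ec, "ECM": ecm}, (1.0, 1.0))
        assert ghost_vessel_fraction(regions) == pytest.approx(0.40)

    def test_extremes(self):
        ecm = np.zeros((10, 10), bool)
        ecm[2:6, 2:6] = True
        full = RegionMaskSet({"EC": np.ones((10, 10), bool), "ECM": ecm}, (1.0, 1.0))
        assert ghost_vessel_fraction(full) == 0.0
        none = RegionMaskSet({"EC": np.zeros((10, 10), bool), "ECM": ecm}, (1.0, 1.0))
        assert ghost_vessel_fraction(none) == 1.0

    def test_empty_ecm_undefined(self):
        regions = RegionMaskSet(
            {"EC": np.ones((5, 5), bool), "ECM": np.zeros((5, 5), bool)}, (1.0, 1.0)
        )
        with pytest.raises(UndefinedFractionError):
            ghost_vessel_fraction(regions)


class TestOracleEquivalence:
    """All area/fraction metrics equal brute-force pixel counting on random
    toy mask pairs (<= 32x32)."""

    @pytest.mark.parametrize("seed", range(6))
    def test_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(8, 33), rng.integers(8, 33))
        ec = rng.random(shape) < 0.3
        peri = rng.random(shape) < 0.3
        ecm = ec | (rng.random(shape) < 0.2)
        regions = RegionMaskSet({"EC": ec, "pericyte": peri, "ECM": ecm}, (1.0, 1.0))
        if ecm.any():
            assert ghost_vessel_fraction(regions) == pytest.approx(brute_ghost_fraction(ecm, ec))
        assert pericyte_coverage(regions) == pytest.approx(brute_coverage_area(peri, ec, 5))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_enlarging_ec_monotone(self, seed):
        """Growing the EC mask never increases the ghost fraction and never
        decreases coverage."""
        rng = np.random.default_rng(seed)
        shape = (16, 16)
        ec = rng.random(shape) < 0.25
        grown = ec | (rng.random(shape) < 0.25)
        peri = rng.random(shape) < 0.3
        ecm = rng.random(shape) < 0.4
        if not ecm.any():
            return
        r1 = RegionMaskSet({"EC": ec, "pericyte": peri, "ECM": ecm}, (1.0, 1.0))
        r2 = RegionMaskSet({"EC": grown, "pericyte": peri, "ECM": ecm}, (1.0, 1.0))
        assert ghost_vessel_fraction(r2) <= ghost_vessel_fraction(r1)
        assert pericyte_coverage(r2) >= pericyte_coverage(r1)


class TestApoptosis:
    def test_viability_arithmetic(self):
        points = [(y, x) for y in range(5, 45, 4) for x in range(5, 45, 5)]
        nuc = _labels_from_points((50, 50), points[:100] if len(points) >= 100 else points)
        n = nuc.count
        k = max(1, n // 20)
        nuc.table.loc[: k - 1, "apoptotic"] = True
        regions = RegionMaskSet({"EC": np.ones((50, 50), bool)}, (1.0, 1.0))
        counts, viability = apoptosis_colocalization(nuc, regions)
        assert viability == pytest.approx(1 - k / n)
        assert counts["EC"] == k  # every nucleus sits on the vessel region

    def test_zero_nuclei_undefined(self):
        nuc = _labels_from_points((10, 10), [])
        regions = RegionMaskSet({"EC": np.ones((10, 10), bool)}, (1.0, 1.0))
        with pytest.raises(UndefinedViabilityError):
            apoptosis_colocalization(nuc, regions)

    def test_flagging_from_reporter_channel(self):
        nuc = _labels_from_points((20, 20), [(5, 5), (15, 15)])
        reporter = np.zeros((20, 20))
        reporter[5, 5] = 0.9
        nuc = flag_apoptotic(nuc, reporter)
        assert list(nuc.table.apoptotic) == [True, False]

    def test_recovers_generator_apoptotic_fraction(self, scene_control_noisy):
        """EC apoptotic fraction measured through the full MIP chain matches
        the preset within a generous binomial margin."""
        from mvnquant.io import max_projection
        from mvnquant.mip import ROLE_TO_MARKER, build_region_masks, normalize_and_smooth

        scene = scene_control_noisy
        images01 = {}
        for role in ("endothelium", "pericyte", "astrocyte", "colIV"):
            img, px = max_projection(scene.stack, role)
            images01[ROLE_TO_MARKER[role]] = normalize_and_smooth(img, clip_max=1.0)
        dapi, px = max_projection(scene.stack, "nuclei")
        apo, _ = max_projection(scene.stack, "apoptosis")
        regions = build_region_masks(images01, px)
        nuc = segment_nuclei(normalize_and_smooth(dapi, clip_max=1.0), px)
        nuc = flag_apoptotic(nuc, normalize_and_smooth(apo, clip_max=1.0))
        counts = assign_nuclei_to_regions(nuc, regions)
        apo_counts, _ = apoptosis_colocalization(nuc, regions)
        measured = apo_counts["EC"] / counts["EC"]
        truth_tt = scene.truth.nuclei_table
        ec_rows = truth_tt[truth_tt.cell_type == "EC"]
        truth_frac = ec_rows.apoptotic.mean()
        n = len(ec_rows)
        margin = 3 * math.sqrt(truth_frac * (1 - truth_frac) / n) + 0.05
        assert abs(measured - truth_frac) <= margin
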