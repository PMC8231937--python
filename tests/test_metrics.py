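"""Per-ROI histograms, means, heat maps, cellularity, vascular density."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumormap import (
    BinaryMask,
    LesionProfile,
    TumorMapError,
    cellularity,
    correlate_density_expression,
    heatmap,
    intensity_histogram,
    mean_intensity,
    vascular_density,
    vessel_distance_map,
)
from tumormap.metrics import FLAG_NO_VESSEL_IN_SECTION

from conftest import brute_force_mean_nearest_distance, channel, roi_from_labels


def single_roi(shape):
    return roi_from_labels(np.ones(shape, np.int32))


class TestHistogram:
    def test_constant_roi_is_delta(self):
        h = intensity_histogram(channel(np.full((8, 8), 100)), single_roi((8, 8)), 1)
        assert h.bins[100] == 100.0
        assert h.bins.sum() == 100.0
        assert np.count_nonzero(h.bins) == 1

    def test_half_and_half(self):
        img = np.zeros((8, 8))
        img[:4] = 255
        h = intensity_histogram(channel(img), single_roi((8, 8)), 1)
        assert h.bins[0] == 50.0 and h.bins[255] == 50.0

    def test_zero_noise_lesion_delta_at_true_mean(self, small_section):
        tm, gt = small_section
        rois = roi_from_labels(gt.roi_labels)
        h = intensity_histogram(tm["her2"], rois, 1)
        assert h.bins[180] == 100.0

    def test_artifact_pixels_excluded(self):
        labels = np.ones((8, 8), np.int32)
        labels[0] = -1
        rois = roi_from_labels(np.where(labels == -1, 0, labels))
        rois.labels[0] = -1
        img = np.full((8, 8), 7)
        img[0] = 250  # artifact row must not contribute
        h = intensity_histogram(channel(img), rois, 1)
        assert h.bins[250] == 0.0
        assert h.n_pixels == 56

    def test_empty_roi_errors(self):
        with pytest.raises(TumorMapError):
            intensity_histogram(channel(np.zeros((4, 4))), single_roi((4, 4)), 9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_conservation_and_two_route_mean(self, seed):
        rng = np.random.default_rng(seed)
        img = channel(rng.integers(0, 256, (16, 16)))
        rois = single_roi((16, 16))
        h = intensity_histogram(img, rois, 1)
        assert abs(h.bins.sum() - 100.0) < 1e-9
        assert abs(h.mean() - mean_intensity(img, rois, 1)) < 1e-9


class TestMean:
    def test_constant(self):
        assert mean_intensity(channel(np.full((5, 5), 42)), single_roi((5, 5)), 1) == 42

    def test_half_half(self):
        img = np.zeros((4, 4))
        img[:2] = 255
        assert mean_intensity(channel(img), single_roi((4, 4)), 1) == 127.5


class TestHeatmap:
    def test_forced_classes_at_default_edges(self):
        img = np.array([[50, 120, 200]])
        rois = single_roi((1, 3))
        hm = heatmap(channel(img), rois)
        assert hm.classes.tolist() == [[1, 2, 3]]

    def test_all_zero_roi_is_weak(self):
        hm = heatmap(channel(np.zeros((4, 4))), single_roi((4, 4)))
        assert (hm.classes == 1).all()

    def test_class_counts_equal_histogram_partial_sums(self, small_section):
        tm, gt = small_section
        rois = roi_from_labels(gt.roi_labels)
        hm = heatmap(tm["her2"], rois, (85, 170))
        for rid in (1, 2):
            h = intensity_histogram(tm["her2"], rois, rid)
            counts = hm.class_counts(rois, rid)
            n = h.n_pixels
            assert counts["weak"] == round(h.bins[:85].sum() * n / 100)
            assert counts["moderate"] == round(h.bins[85:170].sum() * n / 100)
            assert counts["strong"] == round(h.bins[170:].sum() * n / 100)

    def test_invalid_edges_rejected(self):
        with pytest.raises(TumorMapError):
            heatmap(channel(np.zeros((4, 4))), single_roi((4, 4)), (170, 85))


class TestCellularity:
    def _mask(self, arr):
        return BinaryMask(arr, "hoechst", 128, 1)

    def test_full_coverage_is_100(self):
        pct, _ = cellularity(
            self._mask(np.ones((6, 6), bool)),
            channel(np.full((6, 6), 200), "hoechst"), single_roi((6, 6)), 1,
        )
        assert pct == 100.0

    def test_checkerboard_is_50(self):
        board = np.indices((6, 6)).sum(0) % 2 == 0
        pct, _ = cellularity(
            self._mask(board), channel(np.zeros((6, 6)), "hoechst"),
            single_roi((6, 6)), 1,
        )
        assert pct == 50.0

    def test_matches_ground_truth_at_zero_noise(self, small_section):
        from tumormap import mask_nuclei

        tm, gt = small_section
        rois = roi_from_labels(gt.roi_labels)
        nuclei = mask_nuclei(tm["hoechst"], threshold="auto", min_object_px=1)
        for _, row in gt.lesion_table.iterrows():
            pct, _ = cellularity(nuclei, tm["hoechst"], rois, int(row["lesion_id"]))
            assert pct == pytest.approx(100.0 * row["true_nuclei_fraction"], abs=1e-9)


class TestVascularDensity:
    def test_roi_fully_positive_is_zero(self):
        mask = np.ones((5, 5), bool)
        vd = vascular_density(mask, single_roi((5, 5)), 1)
        assert vd.mean_px == 0.0

    def test_center_pixel_hand_value(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        vd = vascular_density(mask, single_roi((3, 3)), 1)
        expected = (4 * 1 + 4 * np.sqrt(2) + 0) / 9
        assert vd.mean_px == pytest.approx(expected, abs=1e-12)

    def test_empty_section_flagged_undefined(self):
        vd = vascular_density(np.zeros((5, 5), bool), single_roi((5, 5)), 1)
        assert np.isnan(vd.mean_px)
        assert FLAG_NO_VESSEL_IN_SECTION in vd.flags

    def test_nearest_vessel_may_lie_outside_roi(self):
        labels = np.zeros((10, 10), np.int32)
        labels[4:7, 4:7] = 1
        rois = roi_from_labels(labels)
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True  # far outside the ROI
        vd = vascular_density(mask, rois, 1)
        assert np.isfinite(vd.mean_px)
        assert "no_vessel_in_roi" in vd.flags

    def test_brute_force_oracle_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            shape = (int(rng.integers(6, 33)), int(rng.integers(6, 33)))
            mask = rng.random(shape) < 0.1
            if not mask.any():
                mask[0, 0] = True
            roi = rng.random(shape) < 0.4
            if not roi.any():
                roi[-1, -1] = True
            rois = roi_from_labels(roi.astype(np.int32))
            vd = vascular_density(mask, rois, 1)
            oracle = brute_force_mean_nearest_distance(mask, roi)
            assert vd.mean_px == pytest.approx(oracle, abs=1e-9)

    def test_scale_covariance_in_um(self):
        mask = np.zeros((8, 8), bool)
        mask[0, 0] = True
        rois = single_roi((8, 8))
        a = vascular_density(mask, rois, 1, pixel_size=0.75)
        b = vascular_density(mask, rois, 1, pixel_size=1.5)
        assert a.mean_px == b.mean_px
        assert b.mean_um == pytest.approx(2 * a.mean_um)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_adding_vessels_never_increases_distance(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16)) < 0.05
        mask[3, 3] = True
        more = mask | (rng.random((16, 16)) < 0.05)
        rois = single_roi((16, 16))
        a = vascular_density(mask, rois, 1)
        b = vascular_density(more, rois, 1)
        assert b.mean_px <= a.mean_px + 1e-12

    def test_torus_wrap_reaches_across_border(self):
        mask = np.zeros((16, 16), bool)
        mask[0, 0] = True
        flat = vessel_distance_map(mask)
        wrapped = vessel_distance_map(mask, wrap=True)
        assert wrapped[15, 15] == pytest.approx(np.sqrt(2), abs=1e-12)
        assert flat[15, 15] == pytest.approx(np.sqrt(2 * 15**2), abs=1e-12)


def _profile(roi_id, density, mean, organ="liver"):
    return LesionProfile(roi_id, organ, {"her2": mean}, 50.0, 100.0,
                         density, density * 0.75)


class TestCorrelation:
    def test_monotone_increasing_rho_one(self):
        profs = [_profile(i, float(i), 10.0 * i) for i in range(1, 6)]
        c = correlate_density_expression(profs, "her2")
        assert c.rho == pytest.approx(1.0)

    def test_monotone_decreasing_rho_minus_one(self):
        profs = [_profile(i, float(i), -10.0 * i + 100) for i in range(1, 6)]
        c = correlate_density_expression(profs, "her2")
        assert c.rho == pytest.approx(-1.0)

    def test_tied_pairs_match_hand_ranked_formula(self):
        # x: 1 2 3 4 5 ; y: 10 20 20 40 50 → mid-ranks for the tie in y
        profs = [
            _profile(1, 1.0, 10.0), _profile(2, 2.0, 20.0), _profile(3, 3.0, 20.0),
            _profile(4, 4.0, 40.0), _profile(5, 5.0, 50.0),
        ]
        rx = np.array([1, 2, 3, 4, 5], float)
        ry = np.array([1, 2.5, 2.5, 4, 5], float)
        hand_rho = np.corrcoef(rx, ry)[0, 1]
        c = correlate_density_expression(profs, "her2")
        assert c.rho == pytest.approx(hand_rho, abs=1e-12)

    def test_too_few_profiles_error(self):
        with pytest.raises(TumorMapError, match="3"):
            correlate_density_expression([_profile(1, 1.0, 5.0)], "her2")

    def test_zero_variance_flagged(self):
        profs = [_profile(i, 2.0, 10.0 * i) for i in range(1, 5)]
        c = correlate_density_expression(profs, "her2")
        assert np.isnan(c.rho)
        assert "zero_variance" in c.flags
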