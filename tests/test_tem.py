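"""Segmentation, fibril detection and windowed-median density estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from corneaquant import tem
from corneaquant.synthetic import FibrilFieldParams, generate_fibril_field

from conftest import truth_centroids_px


def brute_force_threshold(image, window, offset):
    """Independent mean-C oracle: explicit padded neighborhood means."""
    pad = window // 2
    padded = np.pad(image, pad, mode="symmetric")
    out = np.zeros_like(image, dtype=bool)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            local = padded[r : r + window, c : c + window].mean()
            out[r, c] = image[r, c] < local - offset
    return out


class TestBinarizeAdaptive:
    def test_constant_image_all_background(self):
        cfg = tem.SegmentationConfig(offset=0.05)
        mask = tem.binarize_adaptive(np.full((32, 32), 0.5), cfg)
        assert not mask.any()

    def test_matches_brute_force_neighborhood_means(self):
        rng = np.random.default_rng(0)
        image = rng.uniform(0, 1, size=(7, 7))
        image[3, 3] = 0.0  # one dark pixel
        cfg = tem.SegmentationConfig(local_window_px=3, offset=0.05, min_area_px=1)
        assert np.array_equal(
            tem.binarize_adaptive(image, cfg), brute_force_threshold(image, 3, 0.05)
        )

    def test_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(1)
        for window in (3, 5, 9):
            image = rng.uniform(0, 1, size=(16, 16))
            cfg = tem.SegmentationConfig(local_window_px=window, offset=0.02)
            assert np.array_equal(
                tem.binarize_adaptive(image, cfg),
                brute_force_threshold(image, window, 0.02),
            )

    def test_foreground_area_matches_analytic_disk_area(self, clean_field):
        params, field, image = clean_field
        mask = tem.binarize_adaptive(image, tem.SegmentationConfig())
        analytic_px = (np.pi * (field.diameters_nm / 2) ** 2).sum() / params.pixel_size_nm**2
        assert abs(mask.sum() - analytic_px) / analytic_px < 0.05

    def test_multichannel_rejected(self):
        with pytest.raises(ValueError, match="single-channel"):
            tem.binarize_adaptive(np.zeros((4, 4, 3)), tem.SegmentationConfig())

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            tem.SegmentationConfig(local_window_px=4)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(
        lo=st.floats(min_value=0.0, max_value=0.2),
        delta=st.floats(min_value=0.01, max_value=0.2),
    )
    def test_increasing_offset_never_grows_foreground(self, lo, delta):
        rng = np.random.default_rng(42)
        image = rng.uniform(0, 1, size=(24, 24))
        cfg_lo = tem.SegmentationConfig(offset=lo)
        cfg_hi = tem.SegmentationConfig(offset=lo + delta)
        m_lo = tem.binarize_adaptive(image, cfg_lo)
        m_hi = tem.binarize_adaptive(image, cfg_hi)
        assert m_hi.sum() <= m_lo.sum()
        assert not (m_hi & ~m_lo).any()  # nested, not merely smaller


class TestDetectFibrils:
    def test_empty_mask_empty_list(self):
        dets = tem.detect_fibrils(np.zeros((16, 16), bool), 2.0, tem.SegmentationConfig())
        assert dets == []

    def test_ideal_disk_equivalent_diameter(self):
        yy, xx = np.mgrid[:40, :40]
        mask = (xx - 20) ** 2 + (yy - 20) ** 2 <= 10.0**2
        dets = tem.detect_fibrils(mask, 2.0, tem.SegmentationConfig())
        assert len(dets) == 1
        assert dets[0].equivalent_diameter_nm == pytest.approx(40.0, abs=2.0)
        assert dets[0].centroid_px == pytest.approx((20.0, 20.0))
        assert dets[0].circularity <= 1.1

    def test_corner_touching_disks_split_by_connectivity(self):
        mask = np.zeros((9, 9), bool)
        mask[2:4, 2:4] = True
        mask[4:6, 4:6] = True
        base = dict(min_area_px=1, max_area_px=100, min_circularity=0.0)
        n8 = len(tem.detect_fibrils(mask, 2.0, tem.SegmentationConfig(connectivity=8, **base)))
        n4 = len(tem.detect_fibrils(mask, 2.0, tem.SegmentationConfig(connectivity=4, **base)))
        assert (n8, n4) == (1, 2)

    def test_area_and_circularity_filters(self):
        mask = np.zeros((32, 32), bool)
        mask[2, 2] = True  # below min area
        mask[10:12, 4:28] = True  # elongated bar: low circularity
        cfg = tem.SegmentationConfig(min_area_px=4, max_area_px=500, min_circularity=0.6)
        assert tem.detect_fibrils(mask, 2.0, cfg) == []

    def test_noise_free_recovery_count_and_diameters(self, clean_field, clean_detections):
        params, field, _ = clean_field
        dets = clean_detections
        assert len(dets) == field.n_fibrils
        det_rc = np.array([d.centroid_px for d in dets])
        det_d = np.array([d.equivalent_diameter_nm for d in dets])
        dist, idx = cKDTree(det_rc).query(truth_centroids_px(field, params))
        assert dist.max() < 1.0  # every truth fibril matched to a distinct detection
        errors = np.abs(det_d[idx] - field.diameters_nm)
        assert errors.max() <= params.pixel_size_nm


def brute_force_counts(detections, corners, window):
    counts = []
    for r0, c0 in corners:
        n = 0
        for det in detections:
            r, c = det.centroid_px
            if r0 <= r < r0 + window and c0 <= c < c0 + window:
                n += 1
        counts.append(n)
    return np.array(counts)


def fake_detections(centroids):
    return [
        tem.FibrilDetection(
            centroid_px=(float(r), float(c)),
            area_px=100.0,
            perimeter_px=35.0,
            equivalent_diameter_nm=20.0,
            circularity=1.0,
        )
        for r, c in centroids
    ]


class TestEstimateDensity:
    def test_no_detections_zero_density(self):
        est = tem.estimate_density([], (512, 512), 2.0, tem.DensityConfig(seed=0))
        assert est.density_per_um2 == 0.0
        assert len(est.per_window_counts) == 200

    def test_regular_grid_counts_equal_brute_force(self):
        spacing = 25
        grid = [(r, c) for r in range(0, 500, spacing) for c in range(0, 500, spacing)]
        dets = fake_detections(grid)
        cfg = tem.DensityConfig(window_px=100, n_windows=50, seed=7)
        est = tem.estimate_density(dets, (500, 500), 2.0, cfg)
        assert np.array_equal(
            est.per_window_counts, brute_force_counts(dets, est.window_corners_px, 100)
        )

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**20))
    def test_random_fields_counts_equal_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        centroids = rng.uniform(0, 400, size=(rng.integers(0, 150), 2))
        dets = fake_detections(centroids)
        cfg = tem.DensityConfig(window_px=120, n_windows=40, seed=seed)
        est = tem.estimate_density(dets, (400, 400), 2.0, cfg)
        assert np.array_equal(
            est.per_window_counts, brute_force_counts(dets, est.window_corners_px, 120)
        )

    def test_default_protocol_samples_exactly_200_windows_of_300px(self):
        cfg = tem.DensityConfig()
        est = tem.estimate_density([], (1024, 1024), 2.0, cfg)
        assert cfg.n_windows == 200 and cfg.window_px == 300
        assert len(est.per_window_counts) == 200
        assert est.window_px == 300

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            tem.estimate_density([], (200, 200), 2.0, tem.DensityConfig(window_px=300))

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        dets = fake_detections(rng.uniform(0, 512, size=(60, 2)))
        cfg = tem.DensityConfig(seed=21, window_px=128)
        a = tem.estimate_density(dets, (512, 512), 2.0, cfg)
        b = tem.estimate_density(dets, (512, 512), 2.0, cfg)
        assert np.array_equal(a.per_window_counts, b.per_window_counts)
        assert a.density_per_um2 == b.density_per_um2

    def test_density_invariant_holds(self):
        rng = np.random.default_rng(8)
        dets = fake_detections(rng.uniform(0, 512, size=(200, 2)))
        est = tem.estimate_density(dets, (512, 512), 2.0, tem.DensityConfig(window_px=128, seed=1))
        assert est.density_per_um2 == pytest.approx(est.median_count / est.window_area_um2)


def make_estimate(counts, window_px=100, pixel_size_nm=2.0, seed=0):
    counts = np.asarray(counts, dtype=int)
    area = (window_px * pixel_size_nm * 1e-3) ** 2
    med = float(np.median(counts))
    return tem.DensityEstimate(
        per_window_counts=counts,
        window_area_um2=area,
        median_count=med,
        density_per_um2=med / area,
        n_images=1,
        seed=seed,
        window_px=window_px,
        window_corners_px=np.zeros((len(counts), 2), dtype=int),
    )


class TestAggregateDensity:
    def test_identical_estimates_idempotent(self):
        est = make_estimate([2, 3, 4])
        agg = tem.aggregate_density([est, est, est], min_images=3)
        assert agg.density_per_um2 == est.density_per_um2
        assert agg.n_images == 3

    def test_pooled_median_of_listed_counts(self):
        parts = [make_estimate(c) for c in ([0, 0, 1], [2, 2, 3], [1, 1, 2])]
        agg = tem.aggregate_density(parts, min_images=3)
        assert agg.median_count == 1.0
        assert agg.density_per_um2 == pytest.approx(1.0 / agg.window_area_um2)

    def test_too_few_images_rejected_naming_shortfall(self):
        with pytest.raises(ValueError, match="at least 3"):
            tem.aggregate_density([make_estimate([1]), make_estimate([2])], min_images=3)

    def test_mismatched_window_geometry_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            tem.aggregate_density(
                [make_estimate([1]), make_estimate([1], window_px=50), make_estimate([1])],
                min_images=3,
            )


class TestDiameterDistribution:
    def test_single_detection_degenerate_summaries(self):
        det = fake_detections([(0, 0)])[0]
        det.equivalent_diameter_nm = 30.0
        dist = tem.diameter_distribution([det])
        assert dist.median_nm == dist.mean_nm == 30.0
        assert dist.sd_nm == 0.0
        assert dist.iqr_nm == 0.0

    def test_quartiles_with_linear_interpolation(self):
        dets = fake_detections([(i, i) for i in range(4)])
        for det, d in zip(dets, [20.0, 30.0, 40.0, 50.0]):
            det.equivalent_diameter_nm = d
        dist = tem.diameter_distribution(dets)
        assert dist.median_nm == 35.0
        assert dist.iqr_nm == 15.0

    def test_histogram_anchored_at_zero_and_counts_sum(self):
        dets = fake_detections([(i, i) for i in range(7)])
        for det, d in zip(dets, [12.0, 18.0, 22.0, 33.0, 34.0, 35.0, 61.0]):
            det.equivalent_diameter_nm = d
        dist = tem.diameter_distribution(dets, bin_width_nm=10.0)
        assert dist.bin_edges_nm[0] == 0.0
        assert dist.counts.sum() == 7
        assert dist.median_nm == pytest.approx(np.median(dist.diameters_nm))

    def test_empty_input_flagged(self):
        dist = tem.diameter_distribution([])
        assert dist.n == 0
        assert np.isnan(dist.median_nm)

    def test_full_recovery_median_close_to_truth(self, clean_field, clean_detections):
        _, field, _ = clean_field
        dist = tem.diameter_distribution(clean_detections)
        assert abs(dist.median_nm - np.median(field.diameters_nm)) < 2.0


def test_density_recovery_on_generated_field():
    """End-to-end: segmentation + windowed median recovers realized density
    within 10% (median-of-Poisson-counts discretization dominates)."""
    params = FibrilFieldParams(
        target_density=60.0,
        diameter_mean_nm=30.0,
        field_width_px=1024,
        field_height_px=1024,
        pixel_size_nm=2.0,
        noise_sd=0.02,
        seed=17,
    )
    field, image = generate_fibril_field(params)
    seg = tem.SegmentationConfig()
    dets = tem.detect_fibrils(tem.binarize_adaptive(image, seg), 2.0, seg)
    est = tem.estimate_density(dets, image.shape, 2.0, tem.DensityConfig(seed=23))
    rel = abs(est.density_per_um2 - field.realized_density) / field.realized_density
    assert rel <= 0.10
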