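"""Unit and property tests of the detection pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mitoqc import (
    DetectionParams,
    TwoChannelImage,
    build_mask,
    compute_ratio,
    compute_red_threshold,
    detect,
    filter_peaks,
    find_maxima,
    find_maxima_regions,
    median_smooth,
)
from mitoqc.detection import circular_footprint
from mitoqc.synth import random_scene, render_scene

from .oracles import median_filter_oracle, prominence_maxima_oracle


class TestMedianSmooth:
    def test_radius_zero_is_identity(self, rng):
        a = rng.random((7, 9))
        assert np.array_equal(median_smooth(a, 0), a)

    def test_radius_one_kernel_is_full_3x3(self):
        a = np.zeros((3, 3))
        a[1, 1] = 9.0
        out = median_smooth(a, 1)
        assert out[1, 1] == 0.0  # median of {9, eight 0s}

    @pytest.mark.parametrize("radius,expected", [(1, 9), (2, 21), (3, 37)])
    def test_circular_kernel_sizes(self, radius, expected):
        assert circular_footprint(radius).sum() == expected

    def test_matches_sort_oracle(self, rng):
        for _ in range(5):
            a = rng.integers(0, 100, (12, 14)).astype(float)
            for radius in (1, 2):
                assert np.array_equal(
                    median_smooth(a, radius), median_filter_oracle(a, radius)
                )

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            median_smooth(np.zeros((3, 3)), -1)


class TestComputeRatio:
    def test_equal_channels_give_unit_ratio(self, rng):
        chan = rng.random((8, 8)) + 0.5
        img = TwoChannelImage(red=chan, green=chan)
        assert np.allclose(compute_ratio(img, 0), 1.0)

    def test_doubled_red_gives_ratio_two(self, rng):
        g = rng.random((8, 8)) + 0.5
        img = TwoChannelImage(red=2 * g, green=g)
        assert np.allclose(compute_ratio(img, 0), 2.0)

    def test_zero_green_sentinel(self):
        red = np.ones((5, 5))
        green = np.ones((5, 5))
        red[1, 1] = 1.2  # max finite ratio in the image = 1.2
        red[3, 3] = 5.0
        green[3, 3] = 0.0
        ratio = compute_ratio(
            TwoChannelImage(red=red, green=green), 0, ratio_thresh=0.5
        )
        assert ratio[3, 3] == pytest.approx(1.2 + 2 * 0.5)
        assert np.isfinite(ratio).all()

    def test_both_zero_gives_zero(self):
        red = np.zeros((4, 4))
        green = np.zeros((4, 4))
        red[0, 0] = green[0, 0] = 1.0  # keep the image valid and non-empty
        ratio = compute_ratio(TwoChannelImage(red=red, green=green), 0)
        assert ratio[2, 2] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            TwoChannelImage(red=np.ones((4, 4)), green=np.ones((4, 5)))


class TestRedThreshold:
    def test_mean_only(self):
        assert compute_red_threshold(np.array([[0.0, 0.0], [10.0, 10.0]]), 0) == 5.0

    def test_population_std(self):
        # std of {0,0,10,10} with divide-by-N is 5
        assert compute_red_threshold(np.array([[0.0, 0.0], [10.0, 10.0]]), 1) == 10.0

    def test_constant_image_any_k(self):
        assert compute_red_threshold(np.full((3, 3), 7.0), 5.0) == 7.0


class TestFindMaxima:
    def test_flat_image_has_no_maxima(self):
        assert find_maxima(np.ones((6, 6)), 0.5) == []

    def test_single_bright_pixel(self):
        a = np.zeros((9, 9))
        a[4, 4] = 10.0
        assert find_maxima(a, 0.5) == [(4, 4)]

    def test_border_pixels_eligible(self):
        a = np.zeros((5, 5))
        a[0, 0] = 3.0
        assert find_maxima(a, 0.5) == [(0, 0)]

    def test_ridge_merges_below_prominence(self):
        a = np.zeros((5, 7))
        a[2, 1] = a[2, 5] = 10.0
        a[2, 2:5] = 9.8
        assert find_maxima(a, 0.5) == [(1, 2)]
        assert find_maxima(a, 0.1) == [(1, 2), (5, 2)]

    def test_plateau_is_one_candidate_with_lex_min_representative(self):
        a = np.zeros((6, 6))
        a[2:4, 2:4] = 5.0
        regions = find_maxima_regions(a, 1.0)
        assert len(regions) == 1
        assert regions[0] == frozenset({(2, 2), (3, 2), (2, 3), (3, 3)})
        assert find_maxima(a, 1.0) == [(2, 2)]

    def test_nonpositive_prominence_rejected(self):
        with pytest.raises(ValueError):
            find_maxima(np.zeros((3, 3)), 0.0)

    def test_matches_bruteforce_oracle_on_random_rasters(self, rng):
        for _ in range(40):
            shape = rng.integers(4, 25, 2)
            a = rng.integers(0, 21, shape).astype(float)
            prom = float(rng.choice([0.5, 1.0, 1.5, 2.5]))
            assert set(find_maxima_regions(a, prom)) == prominence_maxima_oracle(
                a, prom
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hnp.arrays(np.float64, (8, 8), elements=st.integers(0, 12).map(float)),
        st.sampled_from([0.5, 1.5]),
    )
    def test_shift_invariance_of_maxima(self, a, prom):
        # adding a constant to the raster moves no saddle heights relative
        # to the peaks, so the accepted plateau set is unchanged
        assert set(find_maxima_regions(a, prom)) == set(
            find_maxima_regions(a + 3.25, prom)
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (8, 8), elements=st.integers(0, 12).map(float)))
    def test_accepted_count_non_increasing_in_prominence(self, a):
        counts = [len(find_maxima_regions(a, p)) for p in (0.5, 1.5, 3.0, 6.0)]
        assert counts == sorted(counts, reverse=True)

    def test_python_fallback_agrees_with_public_path(self, rng):
        from mitoqc.detection import _maxima_regions_py

        for _ in range(10):
            a = rng.integers(0, 15, (14, 17)).astype(float)
            flat = a.ravel()
            order = np.argsort(flat, kind="stable")[::-1].astype(np.int64)
            for prom in (0.5, 2.0):
                assert set(_maxima_regions_py(flat, order, 14, 17, prom)) == set(
                    find_maxima_regions(a, prom)
                )

    def test_reported_peaks_are_local_maxima(self, rng):
        for _ in range(20):
            a = rng.integers(0, 15, (12, 12)).astype(float)
            for x, y in find_maxima(a, 1.0):
                neigh = a[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2]
                assert a[y, x] == neigh.max()


class TestFilterAndMask:
    def test_filter_keeps_bright_drops_dim(self):
        red = np.array([[10.0, 1.0], [1.0, 1.0]])
        peaks = [(0, 0), (1, 1)]
        assert filter_peaks(peaks, red, 5.0) == [(0, 0)]
        assert filter_peaks(peaks, red, 0.5) == peaks
        assert filter_peaks(peaks, red, 99.0) == []

    def test_mask_empty_without_peaks(self):
        assert not build_mask(np.ones((4, 4)), [], 0.5, np.ones((4, 4)), 0.0).any()

    def test_mask_single_isolated_pixel(self):
        ratio = np.ones((5, 5))
        ratio[2, 2] = 3.0
        mask = build_mask(ratio, [(2, 2)], 0.5, np.full((5, 5), 9.0), 0.0)
        assert mask.sum() == 1 and mask[2, 2]

    def test_mask_gaussian_punctum_within_tolerance(self):
        # radial Gaussian bump: ratio = 1 + 2*exp(-d^2 / (2*sigma^2))
        sigma = 2.0
        yy, xx = np.mgrid[0:21, 0:21]
        d2 = (xx - 10.0) ** 2 + (yy - 10.0) ** 2
        ratio = 1.0 + 2.0 * np.exp(-0.5 * d2 / sigma**2)
        prominence = 0.6
        mask = build_mask(ratio, [(10, 10)], prominence, np.full_like(ratio, 9.0), 0.0)
        assert np.array_equal(mask, ratio >= 3.0 - prominence)

    def test_mask_respects_red_threshold(self):
        ratio = np.ones((5, 5))
        ratio[2, 1:4] = 3.0
        red = np.full((5, 5), 10.0)
        red[2, 3] = 1.0  # inside the tolerance region but red-dim
        mask = build_mask(ratio, [(1, 2)], 0.5, red, 5.0)
        assert mask[2, 1] and mask[2, 2] and not mask[2, 3]


class TestDetect:
    def test_equal_channels_detect_nothing(self, rng):
        chan = rng.random((32, 32)) + 1.0
        img = TwoChannelImage(red=chan, green=chan)
        res = detect(img, DetectionParams(smooth_radius=0))
        assert res.peaks == [] and not res.mask.any()

    def test_recovers_all_ground_truth_puncta(self, noiseless_scene):
        image, truth, _ = noiseless_scene
        res = detect(image, DetectionParams(smooth_radius=0))
        assert len(res.peaks) == len(truth)
        footprints = [t.footprint for t in truth]
        for peak in res.peaks:
            assert any(peak in fp for fp in footprints)

    def test_bafilomycin_mode_detects_nothing(self):
        spec = random_scene(seed=3, n_puncta=12, quench=0.0, name="baf")
        image, _, _ = render_scene(spec)
        res = detect(image, DetectionParams(smooth_radius=0))
        assert res.peaks == [] and not res.mask.any()

    def test_result_invariants(self):
        spec = random_scene(seed=7, n_puncta=15, noise_sd=6.0, name="noisy")
        image, _, _ = render_scene(spec)
        res = detect(image, DetectionParams())
        red = res.smoothed_red
        for x, y in res.peaks:
            assert res.mask[y, x]
            assert red[y, x] >= res.red_threshold_value
        assert not (res.mask & (red < res.red_threshold_value)).any()

    def test_gain_invariance(self):
        spec = random_scene(seed=9, n_puncta=10, noise_sd=4.0, name="gain")
        image, _, _ = render_scene(spec)
        scaled = TwoChannelImage(
            red=image.red * 3.7, green=image.green * 3.7,
            pixel_size_um=image.pixel_size_um, name="scaled",
        )
        params = DetectionParams()
        a, b = detect(image, params), detect(scaled, params)
        assert a.peaks == b.peaks
        assert np.array_equal(a.mask, b.mask)

    def test_counts_monotone_in_prominence_and_red_offset(self):
        spec = random_scene(seed=13, n_puncta=20, noise_sd=8.0, name="mono")
        image, _, _ = render_scene(spec)
        counts = [
            len(detect(image, DetectionParams(ratio_thresh=p)).peaks)
            for p in (0.2, 0.4, 0.5, 0.6)
        ]
        assert counts == sorted(counts, reverse=True)
        counts_k = [
            len(detect(image, DetectionParams(red_stddev_offset=k)).peaks)
            for k in (-2, 0, 1, 2, 3)
        ]
        assert counts_k == sorted(counts_k, reverse=True)

    def test_mask_area_monotone_on_high_contrast_fixture(self, noiseless_scene):
        image, _, _ = noiseless_scene
        areas = [
            detect(image, DetectionParams(smooth_radius=0, ratio_thresh=p)).mask.sum()
            for p in (0.2, 0.5, 2.0)
        ]
        assert areas == sorted(areas, reverse=True)
        areas_k = [
            detect(image, DetectionParams(smooth_radius=0, red_stddev_offset=k)).mask.sum()
            for k in (-1, 0, 3)
        ]
        assert areas_k == sorted(areas_k, reverse=True)
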