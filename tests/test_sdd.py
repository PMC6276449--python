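"""Threshold-selection module: oracles for every step of the chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sddliver.metrics import dice
from sddliver.sdd import (
    InsufficientClassesError,
    assign_threshold_roles,
    binarize,
    calibrate_params,
    compute_histogram,
    find_thresholds,
    fit_line_slope,
    histogram_modes,
    rescale_intensities,
    slope_difference,
    slope_maxima,
    smooth_histogram,
)


def direct_dft_smooth(hist: np.ndarray, w: int) -> np.ndarray:
    """O(n^2) term-by-term DFT -> band limit -> inverse DFT oracle."""
    n = 255
    f = np.array(
        [sum(hist[x] * np.exp(-2j * np.pi * k * x / n) for x in range(n)) for k in range(n)]
    )
    keep = np.array([min(k, n - k) <= w for k in range(n)])
    f = f * keep
    return np.array(
        [sum(f[k] * np.exp(2j * np.pi * x * k / n) for k in range(n)).real / n for x in range(n)]
    )


def ols_slope(x, y):
    """Normal-equation oracle (B^T B)^-1 B^T Y."""
    b = np.column_stack([x, np.ones(len(x))])
    return np.linalg.solve(b.T @ b, b.T @ np.asarray(y, float))


class TestRescale:
    def test_endpoints_of_affine_map(self):
        out = rescale_intensities(np.array([[0, 1000]]))
        assert out.tolist() == [[1, 255]]

    def test_constant_image_maps_to_255(self):
        out = rescale_intensities(np.full((4, 4), 17))
        assert (out == 255).all()

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            rescale_intensities(np.empty((0, 0)))

    def test_matches_per_pixel_affine_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 4096, (32, 32))
        out = rescale_intensities(img)
        lo, hi = img.min(), img.max()
        oracle = np.rint(1 + 254.0 * (img - lo) / (hi - lo)).astype(int)
        assert np.array_equal(out, oracle)
        # monotone order preserved
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert (np.diff(flat_out[order]) >= 0).all()


class TestHistogram:
    def test_uniform_counts_all_one(self):
        img = np.arange(1, 256).reshape(15, 17)
        assert (compute_histogram(img) == 1.0).all()

    def test_max_normalisation(self):
        img = np.array([100] * 10 + [200] * 5).reshape(3, 5)
        h = compute_histogram(img)
        assert h[99] == 1.0 and h[199] == 0.5 and h.sum() == 1.5

    def test_matches_tally_oracle(self):
        rng = np.random.default_rng(4)
        img = rng.integers(1, 256, (64, 64))
        h = compute_histogram(img)
        tally = np.zeros(255)
        for v in img.ravel():
            tally[v - 1] += 1
        assert np.array_equal(h, tally / tally.max())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_histogram(np.zeros((4, 4), dtype=int))


class TestSmoothing:
    def test_full_band_is_identity(self):
        h = np.random.default_rng(5).random(255)
        assert np.allclose(smooth_histogram(h, 127), h, atol=1e-12)

    def test_constant_histogram_unchanged(self):
        h = np.full(255, 0.3)
        for w in (1, 10, 127):
            assert np.allclose(smooth_histogram(h, w), h, atol=1e-12)

    def test_matches_direct_dft_oracle(self):
        h = np.zeros(255)
        h[100] = 1.0  # single spike
        assert np.allclose(smooth_histogram(h, 10), direct_dft_smooth(h, 10), atol=1e-10)

    def test_idempotent_and_mean_preserving(self):
        h = np.random.default_rng(6).random(255)
        once = smooth_histogram(h, 12)
        assert np.allclose(smooth_histogram(once, 12), once, atol=1e-9)
        assert np.isclose(once.mean(), h.mean())

    @pytest.mark.parametrize("w", [0, 128])
    def test_bandwidth_out_of_range(self, w):
        with pytest.raises(ValueError):
            smooth_histogram(np.ones(255), w)


class TestLineFit:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        a, b = fit_line_slope(x, 3 * x + 1)
        assert np.isclose(a, 3) and np.isclose(b, 1)

    def test_two_points_interpolate(self):
        a, b = fit_line_slope([0, 2], [1, 5])
        assert np.isclose(a, 2) and np.isclose(b, 1)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.random(20) * 10
        y = 2.5 * x - 4 + rng.normal(0, 1, 20)
        a, b = fit_line_slope(x, y)
        oa, ob = ols_slope(x, y)
        assert abs(a - oa) < 1e-9 and abs(b - ob) < 1e-9

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_line_slope([1, 1, 1], [1, 2, 3])


class TestSlopeDifference:
    def test_affine_histogram_gives_zero(self):
        h = np.linspace(0.1, 0.9, 255)
        s = slope_difference(h, 15)
        assert np.abs(s.values).max() < 1e-12

    def test_v_shape_vertex_value(self):
        # arms of slope -m then +m meeting at c: windows lie on single arms
        m, c, n = 0.004, 128, 20
        x = np.arange(1, 256)
        h = m * np.abs(x - c)
        s = slope_difference(h, n)
        i = c - s.first_intensity
        assert np.isclose(s.values[i], 2 * m)

    def test_defined_exactly_on_interior_range(self):
        s = slope_difference(np.random.default_rng(8).random(255), 30)
        assert s.first_intensity == 31 and s.last_intensity == 225
        assert s.values.size == 225 - 31 + 1 == s.intensities().size

    def test_matches_two_window_ols_oracle(self):
        rng = np.random.default_rng(9)
        h = smooth_histogram(rng.random(255), 20)
        n = 15
        s = slope_difference(h, n)
        for i in s.intensities():
            left = ols_slope(np.arange(i - n + 1, i + 1), h[i - n : i])[0]
            right = ols_slope(np.arange(i, i + n), h[i - 1 : i + n - 1])[0]
            assert abs(s.values[i - s.first_intensity] - (right - left)) < 1e-9


def bimodal_hist(mu1=80.0, mu2=180.0, s1=12.0, s2=12.0, w2=1.0):
    x = np.arange(1, 256)
    h = np.exp(-((x - mu1) ** 2) / (2 * s1**2)) + w2 * np.exp(-((x - mu2) ** 2) / (2 * s2**2))
    return h / h.max()


class TestFindThresholds:
    def test_monotone_signal_has_no_valley(self):
        h = np.linspace(0.0, 1.0, 255) ** 2  # strictly convex rising: s > 0 everywhere
        s = slope_difference(smooth_histogram(h, 30), 10)
        # raw candidate scan on a strictly monotone s finds no interior extremum
        assert find_thresholds(slope_difference(np.linspace(0, 1, 255), 10)) == ()

    def test_slope_maxima_match_exhaustive_scan(self):
        # synthetic s built from a cosine histogram: check the raw extrema scan
        x = np.arange(1, 256)
        h = 0.5 + 0.4 * np.cos(2 * np.pi * x / 64.0)
        s = slope_difference(h, 10)
        got = slope_maxima(s)
        v, first = s.values, s.first_intensity
        expected = tuple(
            i + first
            for i in range(1, v.size - 1)
            if v[i] > 0 and v[i] >= v[i - 1] and v[i] >= v[i + 1]
        )
        # merge-free comparison: every exhaustive-scan maximum is reported
        assert got == expected

    def test_two_gaussian_threshold_at_density_intersection(self):
        h = bimodal_hist()
        sm = smooth_histogram(h, 12)
        ts = find_thresholds(slope_difference(sm, 20), sm)
        # equal weight, equal sigma: densities intersect at the midpoint 130
        assert len(ts) == 1 and abs(ts[0] - 130) <= 5

    def test_mode_detection_rejects_ripple(self):
        h = bimodal_hist()
        sm = smooth_histogram(h, 12)
        assert histogram_modes(sm) == (80, 180)


class TestRoleAssignment:
    def test_rank_rule_with_four_valleys(self):
        # class populations: [110,150) is the most populated interior class
        counts = np.zeros(255)
        counts[59] = 3000   # body at 60
        counts[119] = 5000  # liver at 120
        counts[159] = 2000  # organ at 160
        counts[229] = 800   # bone at 230
        ts = assign_threshold_roles((40, 110, 150, 210), counts)
        assert ts.roles == {"T1": 210, "T2": 40, "T3": 150, "T4": 110}

    def test_three_valley_fallback_uses_t1(self):
        ts = assign_threshold_roles((40, 110, 210))
        assert ts.roles == {"T1": 210, "T2": 40, "T3": 210, "T4": 110}

    def test_two_valley_fallback_single_soft_tissue_class(self):
        ts = assign_threshold_roles((40, 180))
        assert ts.roles == {"T1": 180, "T2": 40, "T3": 40, "T4": 40}

    def test_insufficient_classes_error(self):
        with pytest.raises(InsufficientClassesError):
            assign_threshold_roles((100,))

    def test_phantom_structures_recovered_by_assigned_thresholds(self, stomach_phantom):
        img, masks = stomach_phantom
        g = rescale_intensities(img)
        sm = smooth_histogram(compute_histogram(g), 12)
        valleys = find_thresholds(slope_difference(sm, 20), sm)
        counts = np.bincount(g.ravel(), minlength=256)[1:]
        ts = assign_threshold_roles(valleys, counts)
        bones = binarize(g, ts.role("T1"))
        assert dice(bones, masks["bones"]) >= 0.9
        body = binarize(g, ts.role("T2"))
        assert dice(body, masks["body"]) >= 0.95
        # the liver threshold mask covers liver (plus brighter classes)
        liver_plus = binarize(g, ts.role("T4"))
        assert (liver_plus & masks["liver"]).sum() / masks["liver"].sum() >= 0.95


class TestBinarize:
    def test_threshold_one_gives_all_ones(self):
        img = np.random.default_rng(10).integers(1, 256, (8, 8))
        assert binarize(img, 1).all()

    def test_threshold_255_marks_saturated_pixels(self):
        img = np.array([[254, 255], [1, 255]])
        assert binarize(img, 255).tolist() == [[False, True], [False, True]]

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.ones((2, 2), int), 256)

    def test_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(11)
        img = rng.integers(1, 256, (32, 32))
        assert np.array_equal(binarize(img, 128), img >= 128)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=1, max_value=254))
    def test_foreground_count_non_increasing_in_threshold(self, t):
        img = np.random.default_rng(12).integers(1, 256, (16, 16))
        assert binarize(img, t).sum() >= binarize(img, t + 1).sum()


class TestCalibration:
    def test_single_cell_grid_returns_that_cell(self, stomach_phantom):
        img, masks = stomach_phantom
        params = calibrate_params([img], [masks["liver"]], [12], [20])
        assert (params.bandwidth_w, params.window_n) == (12, 20)

    def test_empty_labelled_set_rejected(self):
        with pytest.raises(ValueError):
            calibrate_params([], [], [12], [20])

    def test_matches_exhaustive_grid_oracle(self, stomach_phantom, default_config):
        from sddliver.pipeline import process_slice

        img, masks = stomach_phantom
        w_grid, n_grid = [8, 12], [16, 20]
        params = calibrate_params([img], [masks["liver"]], w_grid, n_grid)
        best, best_score = None, -1.0
        for w in w_grid:
            for n in n_grid:
                cfg = default_config.with_sdd(bandwidth_w=w, window_n=n)
                res = process_slice(img, cfg)
                score = 0.0 if res.empty else dice(res.liver_mask, masks["liver"])
                if score > best_score:
                    best, best_score = (w, n), score
        assert (params.bandwidth_w, params.window_n) == best


def test_valley_position_monotone_in_window_size():
    """On a fixed asymmetric bimodal histogram the detected threshold moves
    monotonically with the line-fit window N."""
    h = bimodal_hist(s2=20.0, w2=0.6)
    sm = smooth_histogram(h, 12)
    positions = []
    for n in range(5, 45, 5):
        ts = find_thresholds(slope_difference(sm, n), sm)
        assert len(ts) == 1
        positions.append(ts[0])
    diffs = np.diff(positions)
    assert (diffs >= 0).all() or (diffs <= 0).all()
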