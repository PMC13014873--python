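import numpy as np
import pytest
from hypothesis import given, strategies as st

from ramansen import analytics, synthgen
from ramansen.analytics import (
    RegionSpec,
    crystallinity,
    fit_trend,
    peak_intensity,
    peak_ratio,
    relative_region_area,
    rgb_channel_means,
    simpson_area,
    spot_size,
    total_integration_time,
)
from ramansen.dataset import DatasetError, Spectrum


def _spec(w, y):
    return Spectrum(np.asarray(w, float), np.asarray(y, float), {})


class TestPeakIntensity:
    def test_on_grid_value(self):
        s = _spec([1002, 1003, 1004], [1, 7, 2])
        assert peak_intensity(s, 1003.0) == 7.0

    def test_off_grid_uses_nearest(self):
        s = _spec([1002, 1003, 1004], [1, 7, 2])
        assert peak_intensity(s, 1003.4) == 7.0

    def test_window_max_matches_brute_force(self):
        w = np.arange(990.0, 1011.0)
        y = np.exp(-0.5 * ((w - 1005.0) / 2.0) ** 2)  # apex at +2 from 1003
        s = _spec(w, y)
        got = peak_intensity(s, 1003.0, window=3.0)
        brute = max(yy for ww, yy in zip(w, y) if 1000.0 <= ww <= 1006.0)
        assert got == brute

    def test_outside_span_errors(self):
        with pytest.raises(DatasetError):
            peak_intensity(_spec([1000, 1001], [1, 1]), 500.0)


class TestRatiosAndCrystallinity:
    def test_ratio_arithmetic(self):
        s = _spec([700.0, 1147.0], [2.0, 4.0])
        assert peak_ratio(s, 700.0, 1147.0) == 0.5

    def test_same_peak_ratio_is_one(self):
        s = _spec([700.0, 1147.0], [2.0, 4.0])
        assert peak_ratio(s, 700.0, 700.0) == 1.0

    def test_zero_denominator_names_wavenumber(self):
        s = _spec([700.0, 1147.0], [2.0, 0.0])
        with pytest.raises(ZeroDivisionError, match="1147"):
            peak_ratio(s, 700.0, 1147.0)

    def test_sol_898_1606_ratio_exceeds_hol(self, templates):
        grid = np.arange(690.0, 1656.0)
        by = {t.class_label: t for t in templates}
        hol = _spec(grid, by["HOL"].clean_signal(grid))
        sol = _spec(grid, by["SOL"].clean_signal(grid))
        assert peak_ratio(sol, 898.0, 1606.0) > peak_ratio(hol, 898.0, 1606.0)

    def test_crystallinity_symmetry(self):
        s = _spec([1462.0, 1481.0], [5.0, 5.0])
        assert crystallinity(s) == 0.5

    def test_crystallinity_limit(self):
        s = _spec([1462.0, 1481.0], [0.0, 3.0])
        assert crystallinity(s) == 1.0

    def test_crystallinity_direct_arithmetic(self):
        s = _spec([1462.0, 1481.0], [60.9, 89.1])
        assert crystallinity(s) == pytest.approx(89.1 / 150.0)
        assert crystallinity(s) == pytest.approx(0.594)

    def test_crystallinity_zero_denominator(self):
        s = _spec([1462.0, 1481.0], [0.0, 0.0])
        with pytest.raises(ZeroDivisionError):
            crystallinity(s)

    @given(st.floats(0.01, 1e6), st.floats(0.0, 1e6), st.floats(1.001, 100.0))
    def test_crystallinity_monotone_in_1481_and_bounded(self, i62, i81, factor):
        s1 = _spec([1462.0, 1481.0], [i62, i81])
        s2 = _spec([1462.0, 1481.0], [i62, i81 * factor])
        x1, x2 = crystallinity(s1), crystallinity(s2)
        assert 0.0 <= x1 <= 1.0
        assert x2 >= x1

    @given(st.floats(0.001, 1e4))
    def test_scale_invariance_of_ratio_and_crystallinity(self, c):
        s = _spec([898.0, 1462.0, 1481.0, 1606.0], [3.0, 2.0, 1.0, 4.0])
        scaled = _spec(s.wavenumbers, c * s.intensities)
        assert peak_ratio(scaled, 898.0, 1606.0) == pytest.approx(peak_ratio(s, 898.0, 1606.0))
        assert crystallinity(scaled) == pytest.approx(crystallinity(s))


class TestSimpson:
    def test_exact_on_quadratic(self):
        x = np.linspace(0.0, 2.0, 5)
        s = _spec(x, x**2)
        assert simpson_area(s) == pytest.approx(8.0 / 3.0, abs=1e-12)

    def test_constant_times_width(self):
        x = np.linspace(0.0, 10.0, 11)
        assert simpson_area(_spec(x, np.full(11, 3.0))) == pytest.approx(30.0)

    def test_sine_closed_form(self):
        x = np.linspace(0.0, np.pi, 101)
        assert simpson_area(_spec(x, np.sin(x))) == pytest.approx(2.0, abs=1e-6)

    def test_exact_on_cubic(self):
        x = np.linspace(0.0, 3.0, 7)
        s = _spec(x, x**3 - 2 * x**2 + x)
        exact = 3.0**4 / 4 - 2 * 3.0**3 / 3 + 3.0**2 / 2
        assert simpson_area(s) == pytest.approx(exact, abs=1e-10)

    def test_odd_interval_count_trapezoid_tail(self):
        # 4 points = 3 intervals: Simpson on first 2 + trapezoid on last.
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = x**2
        expected = 8.0 / 3.0 + 0.5 * (4.0 + 9.0)
        assert simpson_area(_spec(x, y)) == pytest.approx(expected)

    def test_too_few_points_in_region_errors(self):
        s = _spec(np.arange(690.0, 1656.0), np.ones(966))
        with pytest.raises(DatasetError):
            simpson_area(s, RegionSpec("tiny", 700.0, 701.0))

    def test_matches_trapezoid_within_2pct_on_templates(self, templates):
        grid = np.arange(690.0, 1656.0)
        for t in templates:
            y = t.clean_signal(grid)
            simp = simpson_area(_spec(grid, y))
            trap = np.trapezoid(y, grid)
            assert simp == pytest.approx(trap, rel=0.02)


class TestRelativeArea:
    def test_full_range_is_one(self, sim_dataset):
        s = sim_dataset.spectrum(0)
        assert relative_region_area(s, RegionSpec("full", 690.0, 1655.0)) == pytest.approx(1.0)

    def test_disjoint_cover_sums_to_one(self):
        grid = np.arange(690.0, 1656.0)
        rng = np.random.default_rng(5)
        s = _spec(grid, rng.uniform(1.0, 2.0, grid.size))
        # split exactly at a shared grid point: both integrals reuse 1000.0
        a = analytics.simpson_area(s, RegionSpec("lo", 690.0, 1000.0))
        b = analytics.simpson_area(s, RegionSpec("hi", 1000.0, 1655.0))
        total = analytics.simpson_area(s)
        assert (a + b) / total == pytest.approx(1.0, abs=1e-9)

    def test_sol_860_970_fraction_exceeds_hol(self, templates):
        grid = np.arange(690.0, 1656.0)
        by = {t.class_label: t for t in templates}
        region = RegionSpec("860-970", 860.0, 970.0)
        hol = relative_region_area(_spec(grid, by["HOL"].clean_signal(grid)), region)
        sol = relative_region_area(_spec(grid, by["SOL"].clean_signal(grid)), region)
        assert sol > hol

    @given(st.floats(0.01, 100.0))
    def test_relative_area_scale_invariant(self, c):
        grid = np.arange(690.0, 1656.0)
        y = np.ones(grid.size) + (grid > 1000)
        region = RegionSpec("r", 900.0, 1100.0)
        a = relative_region_area(_spec(grid, y), region)
        b = relative_region_area(_spec(grid, c * y), region)
        assert b == pytest.approx(a)


class TestFitTrend:
    def test_exact_linear_r2_one(self):
        x = np.arange(10.0)
        fit = fit_trend(x, 3.0 * x + 1.0, "linear")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.parameters[0] == pytest.approx(3.0)

    def test_exact_exponential_recovery(self):
        x = np.linspace(0.0, 3.0, 20)
        fit = fit_trend(x, 2.0 * np.exp(0.5 * x), "exponential")
        assert fit.parameters[0] == pytest.approx(2.0, rel=1e-6)
        assert fit.parameters[1] == pytest.approx(0.5, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_exponential_b_within_10pct(self):
        # 5 % multiplicative noise, n=100, averaged over 100 seeds.
        x = np.linspace(0.0, 3.0, 100)
        bs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = 2.0 * np.exp(0.5 * x) * (1.0 + rng.normal(0, 0.05, x.size))
            bs.append(fit_trend(x, np.abs(y), "exponential").parameters[1])
        assert np.mean(bs) == pytest.approx(0.5, rel=0.10)

    def test_degenerate_x_errors(self):
        with pytest.raises(ValueError):
            fit_trend([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_nonpositive_y_for_exponential_errors(self):
        with pytest.raises(ValueError):
            fit_trend([1.0, 2.0, 3.0], [1.0, -2.0, 3.0], "exponential")


class TestRgbMeans:
    def test_uniform_image(self):
        img = np.tile(np.array([10, 200, 30], dtype=np.uint8), (4, 4, 1))
        assert rgb_channel_means(img) == (10.0, 200.0, 30.0)

    def test_half_black_half_white(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[1] = 255
        assert rgb_channel_means(img) == (127.5, 127.5, 127.5)

    def test_mask_selects_pixels(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0, 0] = (9, 9, 9)
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        assert rgb_channel_means(img, mask) == (9.0, 9.0, 9.0)

    def test_empty_mask_errors(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            rgb_channel_means(img, np.zeros((2, 2), dtype=bool))

    def test_sol_patch_contract(self):
        img = synthgen.simulate_rgb_patch("SOL", (32, 32), seed=9)
        r, g, _ = rgb_channel_means(img)
        assert r > g


class TestInstrument:
    def test_spot_size_830nm_na04(self):
        assert spot_size(830.0, 0.4) == 2.53

    def test_spot_size_identity_case(self):
        assert spot_size(1000.0, 0.61) == 2.0

    def test_total_integration_time(self):
        assert total_integration_time(5.0, 10) == 50.0

    def test_invalid_na(self):
        with pytest.raises(ValueError):
            spot_size(830.0, 1.5)
        with pytest.raises(ValueError):
            spot_size(-1.0, 0.4)
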