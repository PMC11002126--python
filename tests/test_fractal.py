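"""Fractal-dimension estimators: box counting and spectral."""

import numpy as np
import pytest

from fractalcad import (KOCH_FD, BoxCountingFD, PowerSpectrumFD, box_count,
                        fd_box_counting, fd_power_spectrum, percent_error,
                        power_spectrum, simulate_radial_profile)
from fractalcad.exceptions import (DegenerateSpectrumError,
                                   InvalidParameterError, TooFewScalesError)
from .conftest import box_count_oracle, random_blob


class TestBoxCount:
    def test_single_pixel(self):
        mask = np.zeros((64, 64), np.uint8)
        mask[10, 50] = 1
        series = box_count(mask)
        assert np.all(series.counts == 1)

    def test_full_square(self):
        mask = np.ones((64, 64), np.uint8)
        series = box_count(mask)
        for r, k in zip(series.scales, series.counts):
            assert k == int(np.ceil(64 / r)) ** 2

    def test_horizontal_line_series(self):
        mask = np.zeros((64, 64), np.uint8)
        mask[31, :] = 1
        series = box_count(mask)
        assert list(series.scales) == [64, 32, 16, 8, 4, 2]
        assert list(series.counts) == [1, 2, 4, 8, 16, 32]

    def test_matches_bruteforce_oracle(self):
        """Vectorized counts equal a nested-loop box scanner on 30 random
        masks at every scale."""
        rng = np.random.default_rng(123)
        for i in range(30):
            size = int(rng.integers(24, 65))
            if i % 3 == 0:
                mask = (rng.random((size, size)) < 0.1).astype(np.uint8)
                if not mask.any():
                    mask[0, 0] = 1
            else:
                mask = random_blob(rng, size)
            series = box_count(mask)
            assert list(series.counts) == box_count_oracle(mask, series.scales)

    def test_count_bounds(self):
        rng = np.random.default_rng(7)
        mask = random_blob(rng, 64)
        series = box_count(mask)
        assert np.all(np.diff(series.counts) >= 0)  # K grows as r shrinks
        for r, k in zip(series.scales, series.counts):
            assert k <= np.ceil(64 / r) ** 2

    def test_too_small_image(self):
        with pytest.raises(TooFewScalesError):
            box_count(np.ones((5, 5), np.uint8))


class TestFdBoxCounting:
    def test_straight_line_dimension(self):
        mask = np.zeros((64, 64), np.uint8)
        mask[31, :] = 1
        res = fd_box_counting(mask)
        assert res.fd == pytest.approx(1.0, abs=0.05)

    def test_plane_filling_dimension(self):
        res = fd_box_counting(np.ones((128, 128), np.uint8))
        assert res.fd == pytest.approx(2.0, abs=0.05)

    def test_koch_phantom_within_two_percent(self, koch_outline_1024):
        res = fd_box_counting(koch_outline_1024 > 0)
        assert abs(percent_error(res.fd, KOCH_FD)) <= 2.0

    def test_slope_matches_normal_equations(self, koch_outline_1024):
        """The reported fd reproduces the closed-form least-squares slope."""
        res = fd_box_counting(koch_outline_1024 > 0)
        x, y = res.fit.x, res.fit.y
        n = len(x)
        slope = (n * np.sum(x * y) - x.sum() * y.sum()) / \
                (n * np.sum(x ** 2) - x.sum() ** 2)
        assert res.fd == pytest.approx(slope, abs=1e-9)
        assert res.fit.intercept == pytest.approx(
            (y.sum() - slope * x.sum()) / n, abs=1e-9)

    def test_clamping_preserves_raw_value(self):
        mask = np.zeros((64, 64), np.uint8)
        mask[31, 10:50] = 1  # short line: raw fd may dip below 1
        res = fd_box_counting(mask)
        assert 1.0 <= res.fd_clamped <= 2.0
        if res.fd < 1.0:
            assert any("clamped" in w for w in res.warnings)


class TestPowerSpectrum:
    def test_constant_profile_zero_power(self):
        k, p = power_spectrum(np.full(360, 17.0))
        assert np.all(p <= 1e-18)

    def test_single_cycle_sinusoid(self):
        """One cycle of amplitude a concentrates power (360 a / 2)^2 at k=1
        under the unnormalized transform."""
        a = 2.5
        theta = np.arange(360) * 2 * np.pi / 360
        k, p = power_spectrum(10.0 + a * np.cos(theta))
        assert p[0] == pytest.approx((360 * a / 2) ** 2, rel=1e-9)
        assert np.all(p[1:] < 1e-12 * p[0])

    def test_parseval(self):
        rng = np.random.default_rng(8)
        x = rng.random(360)
        f = np.fft.fft(x)
        assert np.sum(np.abs(f) ** 2) / 360 == pytest.approx(
            np.sum(x ** 2), rel=1e-6)

    def test_nonfinite_rejected(self):
        bad = np.full(360, 1.0)
        bad[5] = np.nan
        with pytest.raises(InvalidParameterError):
            power_spectrum(bad)


class TestFdPowerSpectrum:
    @pytest.mark.parametrize("beta, fd_expected", [(-2.0, 1.0), (0.0, 2.0)])
    def test_slope_to_fd_map(self, beta, fd_expected):
        """The spectral relation maps ß = -2 -> FD 1 and ß = 0 -> FD 2."""
        # deterministic-amplitude profiles make the fitted slope exact
        # (band stops short of the Nyquist bin, whose phase folds into its
        # amplitude)
        prof = simulate_radial_profile(beta, 360, seed=3)
        res = fd_power_spectrum(prof, fit_band=(1, 179))
        assert res.fit.slope == pytest.approx(beta, abs=1e-6)
        assert res.fd == pytest.approx(fd_expected, abs=1e-6)

    def test_monte_carlo_recovery(self):
        """beta = -1.5 profiles average to FD (4 - 1.5)/2 = 1.25."""
        fds = [fd_power_spectrum(simulate_radial_profile(-1.5, 360, s),
                                 fit_band=(1, 180)).fd for s in range(50)]
        assert np.mean(fds) == pytest.approx(1.25, abs=0.08)

    def test_degenerate_spectrum(self):
        with pytest.raises(DegenerateSpectrumError):
            fd_power_spectrum(np.full(360, 30.0))

    def test_classical_relation_mode(self):
        prof = simulate_radial_profile(-2.0, 360, seed=1)
        printed = fd_power_spectrum(prof, fit_band=(1, 180))
        classical = fd_power_spectrum(prof, fit_band=(1, 180),
                                      relation="classical")
        assert classical.fd == pytest.approx(printed.fd + 0.5, abs=1e-6)

    def test_clamped_range_always(self):
        for s in range(10):
            prof = simulate_radial_profile(-2.5, 360, s)
            res = fd_power_spectrum(prof, fit_band=(1, 180))
            assert 1.0 <= res.fd_clamped <= 2.0


class TestPercentError:
    @pytest.mark.parametrize("est, truth, expected", [
        (1.2618, 1.2618, 0.0),
        (1.2774, 1.2618, 1.236),
        (1.2417, 1.2618, -1.593),
    ])
    def test_signed_error(self, est, truth, expected):
        assert percent_error(est, truth) == pytest.approx(expected, abs=5e-4)

    def test_zero_truth(self):
        with pytest.raises(InvalidParameterError):
            percent_error(1.0, 0.0)


class TestEstimatorAPI:
    def test_box_transformer(self, koch_outline_1024):
        est = BoxCountingFD()
        out = est.fit_transform([koch_outline_1024 > 0])
        assert out.shape == (1, 1)
        assert est.results_[0].method == "box_counting"

    def test_spectrum_transformer_fallback(self):
        est = PowerSpectrumFD()
        out = est.fit_transform([np.full(360, 12.0)])
        assert out[0, 0] == 1.0  # smooth-shape fallback
        assert any("fallback" in w for w in est.results_[0].warnings)
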