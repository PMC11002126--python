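"""Phantom generators: Koch snowflake, rasterizer, synthetic nodules and
power-law radial profiles."""

import numpy as np
import pytest

from fractalcad import (KOCH_FD, KochSpec, Polyline, RasterSpec,
                        fd_box_counting, fd_power_spectrum, koch_snowflake,
                        rasterize, simulate_radial_profile,
                        synthetic_nodule_contour)
from fractalcad.exceptions import InvalidParameterError


def _bresenham(r0, c0, r1, c1):
    pts = []
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    r, c = r0, c0
    while True:
        pts.append((r, c))
        if (r, c) == (r1, c1):
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return pts


class TestKochSnowflake:
    @pytest.mark.parametrize("iterations, n_segments",
                             [(0, 3), (1, 12), (2, 48), (3, 192)])
    def test_segment_count(self, iterations, n_segments):
        shape = koch_snowflake(KochSpec(iterations=iterations))
        assert shape.closed
        assert shape.n_segments == n_segments

    @pytest.mark.parametrize("iterations", range(4))
    def test_total_length(self, iterations):
        """Perimeter of iteration k is 3a(4/3)^k for triangle side a."""
        side = 20.0
        shape = koch_snowflake(KochSpec(iterations=iterations, side_mm=side))
        expected = 3 * (3 * side) * (4 / 3) ** iterations
        assert shape.length == pytest.approx(expected, rel=1e-9)

    def test_limiting_dimension_constant(self):
        assert KOCH_FD == pytest.approx(np.log(4) / np.log(3))
        assert KOCH_FD == pytest.approx(1.2618, abs=1e-4)

    def test_first_iteration_bounded_by_hexagon(self):
        """Iteration 1 is a hexagram whose convex hull is a hexagon of the
        configured side: its circumradius equals side_mm * sqrt(3)."""
        side = 20.0
        shape = koch_snowflake(KochSpec(iterations=1, side_mm=side))
        radii = np.linalg.norm(shape.vertices, axis=1)
        assert radii.max() == pytest.approx(side * np.sqrt(3), rel=1e-9)

    def test_invalid_side(self):
        with pytest.raises(InvalidParameterError):
            koch_snowflake(KochSpec(side_mm=0.0))
        with pytest.raises(InvalidParameterError):
            KochSpec(iterations=-1)


class TestRasterize:
    def test_horizontal_segment_pixel_count(self):
        seg = Polyline(np.array([[-32.0, 0.0], [32.0, 0.0]]), closed=False)
        img = rasterize(seg, RasterSpec(80, 80, mm_per_px=1.0))
        rows = np.nonzero((img > 0).any(axis=1))[0]
        assert len(rows) == 1  # one row only
        assert int((img > 0).sum()) == 65

    def test_background_only_canvas(self):
        img = np.full((32, 32), 0, np.uint8)
        assert int((img > 0).sum()) == 0

    def test_deterministic(self):
        shape = koch_snowflake(KochSpec(iterations=2))
        spec = RasterSpec.fit(shape, 256)
        assert np.array_equal(rasterize(shape, spec), rasterize(shape, spec))

    def test_shape_exceeding_canvas(self):
        shape = koch_snowflake(KochSpec(iterations=1, side_mm=20.0))
        with pytest.raises(InvalidParameterError):
            rasterize(shape, RasterSpec(32, 32, mm_per_px=1.0))

    def test_koch_pixel_count_matches_independent_bresenham(self, koch_outline_1024):
        """Foreground count equals an independently drawn Bresenham union."""
        shape = koch_snowflake(KochSpec(iterations=3, side_mm=20.0))
        spec = RasterSpec.fit(shape, 1024)
        v = shape.vertices
        lo, hi = v.min(axis=0), v.max(axis=0)
        center = (lo + hi) / 2
        cols = np.rint((v[:, 0] - center[0]) / spec.mm_per_px
                       + (spec.width_px - 1) / 2).astype(int)
        rows = np.rint((spec.height_px - 1) / 2
                       - (v[:, 1] - center[1]) / spec.mm_per_px).astype(int)
        pix = set()
        for i in range(len(rows)):
            j = (i + 1) % len(rows)
            pix.update(_bresenham(rows[i], cols[i], rows[j], cols[j]))
        assert int((koch_outline_1024 > 0).sum()) == len(pix)


class TestSyntheticNodule:
    def test_zero_amplitude_is_circle(self):
        shape = synthetic_nodule_contour(30.0, 12, 0.0, seed=3)
        radii = np.linalg.norm(shape.vertices, axis=1)
        assert np.allclose(radii, 30.0)

    def test_seed_determinism(self):
        a = synthetic_nodule_contour(40.0, 10, 8.0, seed=11)
        b = synthetic_nodule_contour(40.0, 10, 8.0, seed=11)
        assert np.array_equal(a.vertices, b.vertices)
        c = synthetic_nodule_contour(40.0, 10, 8.0, seed=12)
        assert not np.array_equal(a.vertices, c.vertices)

    def test_amplitude_validation(self):
        with pytest.raises(InvalidParameterError):
            synthetic_nodule_contour(30.0, 8, 30.0, seed=0)
        with pytest.raises(InvalidParameterError):
            synthetic_nodule_contour(-1.0, 8, 1.0, seed=0)

    def test_fd_nondecreasing_with_amplitude(self):
        """More spiculation amplitude cannot lower the contour's
        box-counting FD."""
        spec = RasterSpec(256, 256, mm_per_px=1.0)
        fds = []
        for amp in (0.0, 8.0, 20.0):
            shape = synthetic_nodule_contour(50.0, 12, amp, seed=5)
            img = rasterize(shape, spec, filled=False)
            fds.append(fd_box_counting(img > 0).fd)
        assert fds[0] <= fds[1] + 1e-9
        assert fds[1] <= fds[2] + 1e-9


class TestSimulatedRadialProfile:
    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            simulate_radial_profile(0.5, 360, 0)
        with pytest.raises(InvalidParameterError):
            simulate_radial_profile(-1.0, 15, 0)
        with pytest.raises(InvalidParameterError):
            simulate_radial_profile(-1.0, 21, 0)  # odd

    def test_length_and_finiteness(self):
        p = simulate_radial_profile(-1.5, 360, 7)
        assert p.shape == (360,)
        assert np.all(np.isfinite(p))
        assert np.all(p > 0)

    def test_white_profile_flat_spectrum(self):
        slopes = [fd_power_spectrum(simulate_radial_profile(0.0, 360, s),
                                    fit_band=(1, 180)).fit.slope
                  for s in range(20)]
        assert abs(np.mean(slopes)) < 0.15

    def test_brownian_profile_maps_to_fd_one(self):
        """beta = -2 profiles recover FD = (4 - 2)/2 = 1 on average."""
        fds = [fd_power_spectrum(simulate_radial_profile(-2.0, 360, s),
                                 fit_band=(1, 180)).fd
               for s in range(50)]
        assert np.mean(fds) == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("beta", [-1.0, -1.5, -2.0])
    def test_spectral_slope_recovery(self, beta):
        """Fitted log-log slope converges to the generating exponent."""
        slopes = [fd_power_spectrum(simulate_radial_profile(beta, 360, s),
                                    fit_band=(1, 180)).fit.slope
                  for s in range(50)]
        assert abs(np.mean(slopes) - beta) < 0.15
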