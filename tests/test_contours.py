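import numpy as np
import pytest
from scipy import ndimage

from holoseg.contours import (ChanVeseResult, ContourParams, SnakeContour,
                              evolve_chan_vese, evolve_snake, mask_to_contour,
                              boundary_pixels, refine_partition,
                              snake_image_energy, snake_internal_energy)
from holoseg.errors import (ConvergenceError, DegenerateResultError,
                            ParameterError)
from holoseg.imaging import BinaryMask, RasterImage
from holoseg.peaks import InitialContour


def disk_image(shape=(96, 96), center=(48, 48), radius=20, inside=1.0, outside=0.0):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    disk = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
    arr = np.full(shape, outside)
    arr[disk] = inside
    return RasterImage(arr, "GRAY"), disk


def circle_seed(shape, center, radius):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    disk = ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2)
    return InitialContour(seed_mask=BinaryMask(disk.astype(np.uint8)),
                          center=center)


class TestSnakeInternalEnergy:
    @pytest.mark.parametrize("n_points, radius", [(16, 10.0), (64, 7.5), (128, 20.0)])
    def test_regular_polygon_matches_chord_formula(self, n_points, radius):
        contour = SnakeContour.circle((50.0, 50.0), radius, n_points)
        params = ContourParams(alpha=0.7, beta=0.0)
        expected = 0.7 * n_points * (2.0 * radius * np.sin(np.pi / n_points)) ** 2
        assert snake_internal_energy(contour, params) == pytest.approx(expected, rel=1e-10)

    def test_zero_weights_zero_energy(self):
        contour = SnakeContour.circle((10, 10), 5, 32)
        assert snake_internal_energy(contour, ContourParams(alpha=0, beta=0)) == 0.0

    def test_tension_term_scales_quadratically(self):
        contour = SnakeContour.circle((50, 50), 8, 32)
        doubled = SnakeContour(contour.points * 2.0)
        params = ContourParams(alpha=1.0, beta=0.0)
        assert snake_internal_energy(doubled, params) == pytest.approx(
            4.0 * snake_internal_energy(contour, params), rel=1e-10)


class TestSnakeImageEnergy:
    def test_constant_image_zero(self):
        img = RasterImage(np.full((32, 32), 0.4), "GRAY")
        contour = SnakeContour.circle((16, 16), 5, 16)
        assert snake_image_energy(contour, img) == 0.0

    def test_step_edge_central_difference_value(self):
        # vertical step of height h: central difference gives h/2 on the edge
        h = 0.8
        arr = np.zeros((64, 64))
        arr[:, 32:] = h
        img = RasterImage(arr, "GRAY")
        pts = np.stack([np.linspace(5, 58, 20), np.full(20, 32.0)], axis=1)
        energy = snake_image_energy(SnakeContour(pts), img)
        assert energy == pytest.approx(-20 * h / 2.0, rel=1e-10)

    def test_energy_drops_when_points_move_onto_edge(self):
        arr = np.zeros((64, 64))
        arr[:, 32:] = 1.0
        img = RasterImage(arr, "GRAY")
        flat = SnakeContour(np.stack([np.linspace(5, 58, 20), np.full(20, 10.0)], axis=1))
        edge = SnakeContour(np.stack([np.linspace(5, 58, 20), np.full(20, 32.0)], axis=1))
        assert snake_image_energy(edge, img) < snake_image_energy(flat, img)


class TestEvolveSnake:
    def test_no_forces_keeps_contour_stationary(self):
        img = RasterImage(np.full((64, 64), 0.5), "GRAY")
        init = SnakeContour.circle((32, 32), 10, 32)
        params = ContourParams(alpha=0.0, beta=0.0, max_iter=5)
        out, history = evolve_snake(init, img, params)
        np.testing.assert_allclose(out.points, init.points, atol=1e-9)

    def test_infinite_tolerance_single_iteration(self):
        img = RasterImage(np.full((64, 64), 0.5), "GRAY")
        init = SnakeContour.circle((32, 32), 10, 32)
        params = ContourParams(alpha=0.1, beta=0.1, tol=np.inf, max_iter=50)
        _, history = evolve_snake(init, img, params)
        assert len(history) == 2  # initial energy + one iteration

    def test_circle_converges_onto_disk_edge(self):
        img, disk = disk_image(radius=20)
        init = SnakeContour.circle((48.0, 48.0), 26.0, 80)
        params = ContourParams(alpha=0.02, beta=0.02, edge_sigma=3.0,
                               snake_dt=1.0, max_iter=400, tol=1e-10)
        out, history = evolve_snake(init, img, params)
        radii = np.hypot(out.points[:, 0] - 48.0, out.points[:, 1] - 48.0)
        assert np.mean(np.abs(radii - 20.0)) < 1.0

    def test_divergence_raises_with_last_stable_state(self):
        img = RasterImage(np.full((64, 64), 0.5), "GRAY")
        init = SnakeContour.circle((32, 32), 10, 32)
        params = ContourParams(alpha=1.0, beta=0.0, balloon=2.0,
                               snake_dt=0.5, max_iter=100, tol=1e-12)
        with pytest.raises(ConvergenceError) as excinfo:
            evolve_snake(init, img, params)
        assert isinstance(excinfo.value.last_state, SnakeContour)

    def test_too_few_points_rejected(self):
        img = RasterImage(np.full((64, 64), 0.5), "GRAY")
        with pytest.raises(ParameterError):
            evolve_snake(SnakeContour.circle((32, 32), 5, 4), img)


class TestChanVese:
    def test_two_valued_disk_recovered(self):
        img, disk = disk_image()
        seed = circle_seed((96, 96), (48, 48), 8)
        mask = evolve_chan_vese(img, seed)
        inter = np.sum(mask.pixels.astype(bool) & disk)
        dice = 2.0 * inter / (mask.area() + disk.sum())
        assert dice >= 0.98

    def test_constant_image_degenerate(self):
        img = RasterImage(np.full((64, 64), 0.3), "GRAY")
        with pytest.raises(DegenerateResultError):
            evolve_chan_vese(img, circle_seed((64, 64), (32, 32), 6))

    def test_region_means_are_fixed_point(self):
        img, _ = disk_image()
        res = evolve_chan_vese(img, circle_seed((96, 96), (48, 48), 8),
                               full_output=True)
        inside = res.mask.pixels.astype(bool)
        assert res.c1 == pytest.approx(img.pixels[inside].mean(), abs=1e-6)
        assert res.c2 == pytest.approx(img.pixels[~inside].mean(), abs=1e-6)

    def test_energy_history_non_increasing(self):
        img, _ = disk_image(inside=0.9, outside=0.2)
        res = evolve_chan_vese(img, circle_seed((96, 96), (48, 48), 8),
                               full_output=True)
        e = np.array(res.energy_history)
        assert np.all(np.diff(e) <= 1e-9)

    def test_invariant_under_intensity_inversion(self, rng):
        arr = np.full((96, 96), 0.2) + 0.01 * rng.random((96, 96))
        yy, xx = np.mgrid[:96, :96]
        arr[(yy - 40) ** 2 + (xx - 55) ** 2 <= 15 ** 2] = 0.85
        seed = circle_seed((96, 96), (40, 55), 6)
        m1 = evolve_chan_vese(RasterImage(arr, "GRAY"), seed)
        m2 = evolve_chan_vese(RasterImage(1.0 - arr, "GRAY"), seed)
        np.testing.assert_array_equal(m1.pixels, m2.pixels)

    def test_deterministic(self, rng):
        arr = np.full((96, 96), 0.2) + 0.02 * rng.random((96, 96))
        yy, xx = np.mgrid[:96, :96]
        arr[(yy - 48) ** 2 + (xx - 48) ** 2 <= 18 ** 2] = 0.8
        img = RasterImage(arr, "GRAY")
        seed = circle_seed((96, 96), (48, 48), 7)
        m1 = evolve_chan_vese(img, seed)
        m2 = evolve_chan_vese(img, seed)
        np.testing.assert_array_equal(m1.pixels, m2.pixels)

    def test_empty_seed_rejected(self):
        img, _ = disk_image()
        with pytest.raises(ParameterError):
            InitialContour(seed_mask=BinaryMask(np.zeros((96, 96), np.uint8)),
                           center=(48, 48))

    def test_refine_partition_strictly_decreases_hard_energy(self, rng):
        from holoseg.contours import chan_vese_energy
        arr = np.full((64, 64), 0.2) + 0.05 * rng.random((64, 64))
        yy, xx = np.mgrid[:64, :64]
        arr[(yy - 32) ** 2 + (xx - 32) ** 2 <= 12 ** 2] = 0.8
        params = ContourParams()
        rough = (yy - 32) ** 2 + (xx - 32) ** 2 <= 16 ** 2  # too-large mask
        e0, _, _ = chan_vese_energy(arr, rough, params)
        refined = refine_partition(arr, rough, params)
        e1, _, _ = chan_vese_energy(arr, refined, params)
        assert e1 <= e0


class TestMaskToContour:
    def test_square_boundary_has_eight_ordered_pixels(self):
        mask = np.zeros((10, 10), np.uint8)
        mask[3:6, 4:7] = 1
        contour = mask_to_contour(BinaryMask(mask))
        assert len(contour) == 8
        # consecutive trace points are 8-adjacent, closing the loop
        pts = contour.points
        gaps = np.abs(np.roll(pts, -1, axis=0) - pts).max(axis=1)
        assert gaps.max() <= 1.0

    def test_single_pixel(self):
        mask = np.zeros((8, 8), np.uint8)
        mask[4, 5] = 1
        contour = mask_to_contour(BinaryMask(mask))
        assert len(contour) == 1
        np.testing.assert_array_equal(contour.points[0], [4, 5])

    def test_boundary_pixels_have_background_neighbour(self, rng):
        mask = np.zeros((32, 32), np.uint8)
        yy, xx = np.mgrid[:32, :32]
        mask[(yy - 16) ** 2 + (xx - 14) ** 2 <= 8 ** 2] = 1
        for r, c in boundary_pixels(BinaryMask(mask)):
            neigh = [mask[r + dr, c + dc] for dr, dc in
                     ((1, 0), (-1, 0), (0, 1), (0, -1))
                     if 0 <= r + dr < 32 and 0 <= c + dc < 32]
            assert 0 in neigh or r in (0, 31) or c in (0, 31)

    def test_empty_mask_rejected(self):
        with pytest.raises(ParameterError):
            mask_to_contour(BinaryMask(np.zeros((8, 8), np.uint8)))

    def test_largest_component_traced(self):
        mask = np.zeros((16, 16), np.uint8)
        mask[2:9, 2:9] = 1  # 49 px
        mask[12, 12] = 1  # distractor
        contour = mask_to_contour(BinaryMask(mask))
        assert contour.points[:, 0].max() <= 8
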