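"""Whole-slide scanning and stitching: flat-field correction, keypoint
pair registration, mosaic composition and the naive tiling baseline."""

from __future__ import annotations

import numpy as np
import pytest

from wedgescan import NoiseModel, OpticalConfig, VirtualMicroscope, geometry as g, make_phantom
from wedgescan import ws_mosaic as wm
from wedgescan.specs import AreaSensorSpec, SystemConfig
from wedgescan.demo import demo_system


@pytest.fixture(scope="module")
def stitch_system():
    """Instrument with a mid-size RGB sensor, enough for dense keypoints."""
    base = demo_system()
    rgb = AreaSensorSpec(width_px=192, height_px=256, pixel_pitch_um=2.4, bit_depth=12)
    return SystemConfig(wedge=base.wedge, rgb=rgb, magnifications=base.magnifications)


@pytest.fixture(scope="module")
def dense_phantom():
    """Densely covered tissue slide (the regime whole-slide scans target)."""
    return make_phantom(31, extent_um=(700.0, 700.0), n_classes=3, grid_um=0.5,
                        focus_amplitude_um=0.0, blob_density=4e-4)


def _grid(system, n_cols=3, n_rows=2):
    fov = g.field_of_view(system.rgb, system.magnification(4.0))
    origin = (350.0 + (n_cols / 2) * fov[1] / 2, 350.0 + (n_rows / 2) * fov[0] / 2)
    end = (origin[0] - n_cols * fov[1] / 2, origin[1] - n_rows * fov[0] / 2)
    return g.tile_grid(origin, end, fov)


def _microscope(phantom, system, mis=0.0, noise=None, vignette=0.15, seed=31):
    mic = VirtualMicroscope(
        phantom, system,
        optics=OpticalConfig(misalignment_deg=mis, vignette_strength=vignette),
        noise=noise if noise is not None else NoiseModel(rng_seed=seed))
    mic.move_to(z_um=470.0)
    return mic


class TestFlatField:
    def test_tile_equal_to_white_becomes_uniform(self):
        rng = np.random.default_rng(0)
        white = rng.uniform(100, 4000, (16, 12, 3))
        out = wm.flat_field(white, white)
        np.testing.assert_allclose(out, white.max())

    def test_removes_simulated_vignetting(self, dense_phantom, stitch_system):
        mic = _microscope(dense_phantom, stitch_system, vignette=0.25,
                          noise=NoiseModel.noiseless())
        tile = mic.capture_rgb_white(4.0).astype(float)  # pure vignette field
        white = mic.capture_rgb_white(4.0).astype(float)
        out = wm.flat_field(tile, white)
        corner = out[:8, :8].mean()
        center = out[124:132, 92:100].mean()
        assert abs(corner / center - 1.0) < 0.02

    def test_idempotent_on_flat_tile(self):
        flat = np.full((8, 8, 3), 1000.0)
        white = np.full((8, 8, 3), 2000.0)
        once = wm.flat_field(flat, white)
        twice = wm.flat_field(once, white)
        np.testing.assert_allclose(twice, once)

    def test_zero_white_pixels_flagged_and_zeroed(self):
        white = np.full((4, 4, 3), 500.0)
        white[0, 0] = 0.0
        out = wm.flat_field(np.full((4, 4, 3), 250.0), white)
        assert np.all(out[0, 0] == 0.0)
        assert np.all(out[1:] > 0.0)


class TestRunWSScan:
    def test_snake_capture_of_full_grid(self, dense_phantom, stitch_system):
        grid = _grid(stitch_system, 3, 2)
        mic = _microscope(dense_phantom, stitch_system)
        stack = wm.run_ws_scan(mic, grid, 4.0)
        assert len(stack.tiles) == 6
        assert stack.grid.snake_order[:3] == [(0, 0), (0, 1), (0, 2)]
        assert stack.grid.snake_order[3:] == [(1, 2), (1, 1), (1, 0)]
        assert stack.white_image is not None
        assert stack.scan_info["n_total"] == 6

    def test_adjacent_tiles_share_identical_overlap_halves(self, dense_phantom,
                                                           stitch_system):
        # zero misalignment, zero noise, no vignette: construction guarantees
        # the bottom half of a tile equals the top half of the next
        grid = _grid(stitch_system, 2, 1)
        mic = _microscope(dense_phantom, stitch_system, mis=0.0, vignette=0.0,
                          noise=NoiseModel.noiseless())
        stack = wm.run_ws_scan(mic, grid, 4.0)
        tiles = stack.by_grid()
        h = stitch_system.rgb.height_px
        np.testing.assert_array_equal(tiles[(0, 0)][h // 2:], tiles[(0, 1)][: h // 2])

    def test_grid_outside_phantom_rejected_before_capture(self, dense_phantom,
                                                          stitch_system):
        fov = g.field_of_view(stitch_system.rgb, stitch_system.magnification(4.0))
        grid = g.tile_grid((10.0, 350.0), (-300.0, 450.0), fov)
        mic = _microscope(dense_phantom, stitch_system)
        with pytest.raises(ValueError, match="outside"):
            wm.run_ws_scan(mic, grid, 4.0)


@pytest.fixture(scope="module")
def scene(dense_phantom, stitch_system):
    """One tall noiseless strip of scene used to crop synthetic tile pairs."""
    mic = _microscope(dense_phantom, stitch_system, mis=0.0, vignette=0.0,
                      noise=NoiseModel.noiseless())
    big = AreaSensorSpec(width_px=192, height_px=512, pixel_pitch_um=2.4,
                         bit_depth=12)
    return mic.capture_rgb(4.0, sensor=big).astype(float)


class TestEstimatePairAffine:
    def test_half_shifted_crop_recovers_pure_translation(self, scene):
        a, b = scene[:256], scene[128:384]
        pair = wm.estimate_pair_affine(a, b, "vertical")
        assert pair.translation[0] == pytest.approx(128.0, abs=0.05)
        assert pair.translation[1] == pytest.approx(0.0, abs=0.05)
        assert abs(pair.rotation_deg) < 0.01

    def test_identical_images_give_identity(self, scene):
        a = scene[:256]
        pair = wm.estimate_pair_affine(a, a, "full")
        np.testing.assert_array_equal(pair.matrix,
                                      np.array([[1.0, 0, 0], [0, 1.0, 0]]))

    def test_chained_transforms_match_direct_estimate(self, scene):
        # quarter-height steps so the far pair still shares half its content
        a, b, c = scene[:256], scene[64:320], scene[128:384]
        t_ab = wm.estimate_pair_affine(a, b, "vertical", nominal_offset_px=(64, 0))
        t_bc = wm.estimate_pair_affine(b, c, "vertical", nominal_offset_px=(64, 0))
        t_ac = wm.estimate_pair_affine(a, c, "vertical", nominal_offset_px=(128, 0))
        chained = wm._compose(t_ab.matrix, t_bc.matrix)
        assert np.abs(chained[:, 2] - t_ac.matrix[:, 2]).max() < 1.0

    def test_low_texture_overlap_raises(self):
        flat = np.full((64, 48, 3), 1000.0)
        with pytest.raises(wm.LowTextureError):
            wm.estimate_pair_affine(flat, flat, "vertical")

    def test_mount_rotation_recovered_from_translation_drift(self, dense_phantom,
                                                             stitch_system):
        grid = _grid(stitch_system, 3, 2)
        mic = _microscope(dense_phantom, stitch_system, mis=0.3)
        stack = wm.run_ws_scan(mic, grid, 4.0)
        tiles = {k: wm.flat_field(v, stack.white_image)
                 for k, v in stack.by_grid().items()}
        h = stitch_system.rgb.height_px
        angles = []
        for r in range(2):
            for c in range(2):
                pair = wm.estimate_pair_affine(tiles[(r, c)], tiles[(r, c + 1)],
                                               "vertical")
                angles.append(pair.implied_rotation_deg((h / 2, 0.0)))
        assert abs(abs(np.mean(angles)) - 0.3) <= 0.05


class TestComposeMosaic:
    def test_single_tile_mosaic_is_the_tile(self, dense_phantom, stitch_system):
        fov = g.field_of_view(stitch_system.rgb, stitch_system.magnification(4.0))
        grid = g.TileGrid(n_cols=1, n_rows=1, origin_um=(350.0, 350.0),
                          end_um=(350.0 - fov[1] / 2, 350.0 - fov[0] / 2),
                          col_step_um=-fov[1] / 2, row_step_um=-fov[0] / 2,
                          snake_order=[(0, 0)])
        mic = _microscope(dense_phantom, stitch_system, mis=0.0,
                          noise=NoiseModel.noiseless())
        stack = wm.run_ws_scan(mic, grid, 4.0)
        result = wm.compose_mosaic(stack, apply_flat_field=False)
        np.testing.assert_array_equal(result.image,
                                      stack.tiles[0].astype(float))

    def test_zero_misalignment_mosaic_equals_direct_render(self, dense_phantom,
                                                           stitch_system):
        grid = _grid(stitch_system, 3, 2)
        mic = _microscope(dense_phantom, stitch_system, mis=0.0, vignette=0.0,
                          noise=NoiseModel.noiseless())
        stack = wm.run_ws_scan(mic, grid, 4.0)
        result = wm.compose_mosaic(stack, apply_flat_field=False)
        h, w = 256, 192
        big = AreaSensorSpec(width_px=w + w // 2, height_px=h + 2 * (h // 2),
                             pixel_pitch_um=2.4, bit_depth=12)
        centers = [grid.stage_position(r, c) for r in range(2) for c in range(3)]
        mic.move_to(x_um=float(np.mean([p[0] for p in centers])),
                    y_um=float(np.mean([p[1] for p in centers])))
        truth = mic.capture_rgb(4.0, sensor=big).astype(float)
        assert result.composition_log == []  # every pair actually fitted
        assert result.image.shape[:2] >= truth.shape[:2]
        np.testing.assert_array_equal(result.image[: truth.shape[0], : truth.shape[1]],
                                      truth)

    def test_deterministic_given_seed(self, dense_phantom, stitch_system):
        grid = _grid(stitch_system, 2, 2)
        mic = _microscope(dense_phantom, stitch_system, mis=0.3)
        stack = wm.run_ws_scan(mic, grid, 4.0)
        a = wm.compose_mosaic(stack, seed=7)
        b = wm.compose_mosaic(stack, seed=7)
        np.testing.assert_array_equal(a.image, b.image)

    def test_failed_pairs_fall_back_to_nominal_and_are_logged(self, stitch_system):
        # an empty slide has no keypoints anywhere
        ph = make_phantom(40, extent_um=(700.0, 700.0), n_classes=2, grid_um=1.0,
                          focus_amplitude_um=0.0)
        ph.label_map[:] = 0
        grid = _grid(stitch_system, 2, 1)
        mic = _microscope(ph, stitch_system, mis=0.0, noise=NoiseModel.noiseless())
        stack = wm.run_ws_scan(mic, grid, 4.0)
        result = wm.compose_mosaic(stack, apply_flat_field=False)
        assert len(result.composition_log) == 1
        pair = next(iter(result.pair_transforms.values()))
        assert pair.fallback
        np.testing.assert_array_equal(pair.translation, (128.0, 0.0))


class TestTilingBaseline:
    def test_no_overlap_plan_needs_about_a_quarter_of_the_tiles(self, stitch_system):
        fov = g.field_of_view(stitch_system.rgb, stitch_system.magnification(4.0))
        origin, end = (600.0, 600.0), (100.0, 150.0)
        half = g.tile_grid(origin, end, fov)
        full = wm.plan_tiling_grid(origin, end, fov)
        assert full.n_cols == int(np.ceil(half.n_cols / 2))
        assert full.n_rows == int(np.ceil(half.n_rows / 2))

    def test_zero_misalignment_baseline_matches_direct_render(self, dense_phantom,
                                                              stitch_system):
        fov = g.field_of_view(stitch_system.rgb, stitch_system.magnification(4.0))
        h, w = 256, 192
        origin = (350.0 + fov[1], 350.0 + fov[0])
        end = (origin[0] - 2 * fov[1], origin[1] - 2 * fov[0])
        grid = wm.plan_tiling_grid(origin, end, fov)
        mic = _microscope(dense_phantom, stitch_system, mis=0.0, vignette=0.0,
                          noise=NoiseModel.noiseless())
        stack = wm.run_ws_scan(mic, grid, 4.0)
        baseline = wm.compose_tiling_baseline(stack)
        big = AreaSensorSpec(width_px=grid.n_rows * w, height_px=grid.n_cols * h,
                             pixel_pitch_um=2.4, bit_depth=12)
        centers = [grid.stage_position(r, c)
                   for r in range(grid.n_rows) for c in range(grid.n_cols)]
        mic.move_to(x_um=float(np.mean([p[0] for p in centers])),
                    y_um=float(np.mean([p[1] for p in centers])))
        truth = mic.capture_rgb(4.0, sensor=big).astype(float)
        np.testing.assert_array_equal(baseline, truth)


def test_ncc_of_identical_images_is_one():
    rng = np.random.default_rng(1)
    img = rng.uniform(0, 1, (32, 32))
    assert wm.ncc(img, img) == pytest.approx(1.0)
    assert wm.ncc(img, -img) == pytest.approx(-1.0)
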