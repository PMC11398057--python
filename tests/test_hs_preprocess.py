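"""Preprocessing chain: Eq.-style radiometric calibration, band-by-band cube
composition (checked against a brute-force coverage oracle), spectral
correction, rotation, ENVI round trips and the pseudo-RGB preview."""

from __future__ import annotations

import numpy as np
import pytest

from wedgescan import NoiseModel, OpticalConfig
from wedgescan.hs_acquisition import RawHSScan, ScanInfoRecord, plan_hs_scan, run_hs_scan, save_raw
from wedgescan.hs_preprocess import (
    CalibrationSet,
    HSCube,
    calibrate_frame,
    compose_cube,
    pseudo_rgb,
    preprocess_chain,
    read_envi,
    rotate_cube_ccw,
    spectral_correct,
    write_envi,
)
from wedgescan.simulator import reference_calibration
from wedgescan.specs import WedgeSensorSpec


class TestCalibrateFrame:
    W = np.full((4, 5), 900.0)
    D = np.full((4, 5), 20.0)

    def test_raw_equal_white_gives_unity(self):
        np.testing.assert_array_equal(calibrate_frame(self.W, self.W, self.D), 1.0)

    def test_raw_equal_dark_gives_zero(self):
        np.testing.assert_array_equal(calibrate_frame(self.D, self.W, self.D), 0.0)

    def test_midpoint_gives_half(self):
        mid = (self.W + self.D) / 2.0
        np.testing.assert_array_equal(calibrate_frame(mid, self.W, self.D), 0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            calibrate_frame(np.zeros((3, 3)), self.W, self.D)

    def test_non_positive_denominator_flagged_invalid(self):
        white = self.W.copy()
        white[0, 0] = 10.0  # below dark
        t, valid = calibrate_frame(self.W, white, self.D, return_valid=True)
        assert not valid[0, 0] and t[0, 0] == 0.0
        assert valid[1:].all()

    def test_inversion_recovers_raw_on_valid_pixels(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(50, 800, (6, 7))
        t = calibrate_frame(raw, self.W[:1, :1] * np.ones((6, 7)), np.full((6, 7), 20.0))
        np.testing.assert_allclose(t * (900.0 - 20.0) + 20.0, raw, rtol=1e-12)


def _tiny_spec(n_bands: int = 3, bh: int = 2, width: int = 10,
               mask=None) -> WedgeSensorSpec:
    return WedgeSensorSpec(
        width_px=width, height_px=n_bands * bh, band_height_px=bh,
        n_theoretical_bands=n_bands,
        n_useful_bands=int(np.sum(mask)) if mask is not None else n_bands,
        useful_band_mask=mask, pixel_pitch_um=5.5)


def _identity_calibration(spec: WedgeSensorSpec, white_level: float = 1000.0
                          ) -> CalibrationSet:
    useful = spec.useful_indices
    wl = spec.band_wavelengths_nm[useful]
    order = np.argsort(wl)
    perm = np.zeros((useful.size, useful.size))
    perm[np.arange(useful.size), order] = 1.0
    return CalibrationSet(
        white_frame=np.full((spec.height_px, spec.width_px), white_level),
        dark_frame=np.zeros((spec.height_px, spec.width_px)),
        spectral_correction=perm,
        corrected_wavelengths_nm=wl[order],
    )


def _synthetic_scan(spec: WedgeSensorSpec, n_frames: int) -> RawHSScan:
    """Frames encoding ground truth: the rows of sensor block k in frame f
    image scene strip f + k, and carry the value 10·strip + k."""
    n_th, bh = spec.n_theoretical_bands, spec.band_height_px
    frames = np.zeros((n_frames, spec.height_px, spec.width_px), dtype=np.uint16)
    for f in range(n_frames):
        for k in range(n_th):
            frames[f, k * bh:(k + 1) * bh, :] = 10 * (f + k) + k
    info = ScanInfoRecord(sample_id="syn", magnification=10.0, n_frames=n_frames,
                          step_um=1.0, start_xy_um=(0.0, 0.0),
                          end_xy_um=(n_frames, 0.0), z_um=0.0)
    return RawHSScan(frames=frames, info=info)


def _oracle_cube(spec: WedgeSensorSpec, n_frames: int) -> np.ndarray:
    """Exhaustively track which scene strip each band of each frame saw and
    assemble the expected (calibrated) cube from the fully-covered strips.

    The composer drops the final covered strip (completed only by the very
    last frame), hence the ``[:-1]``.
    """
    n_th, bh = spec.n_theoretical_bands, spec.band_height_px
    seen: dict[int, dict[int, float]] = {}
    for f in range(n_frames):
        for k in range(n_th):
            band = n_th - 1 - k  # trailing-edge band indexing
            seen.setdefault(f + k, {})[band] = (10 * (f + k) + k) / 1000.0
    covered = sorted(s for s, bands in seen.items() if len(bands) == n_th)[:-1]
    useful = spec.useful_indices
    cube = np.empty((len(covered) * bh, spec.width_px, useful.size), dtype=np.float32)
    for i, strip in enumerate(covered):
        for u, band in enumerate(useful):
            cube[i * bh:(i + 1) * bh, :, u] = seen[strip][int(band)]
    return cube


class TestComposeCube:
    @pytest.mark.parametrize("n_bands, bh, n_frames", [
        (3, 2, 6), (3, 2, 10), (5, 1, 14), (8, 2, 21),
    ])
    def test_matches_brute_force_oracle(self, n_bands, bh, n_frames):
        spec = _tiny_spec(n_bands, bh)
        scan = _synthetic_scan(spec, n_frames)
        cube = compose_cube(scan, _identity_calibration(spec), spec)
        np.testing.assert_allclose(cube.data, _oracle_cube(spec, n_frames),
                                   rtol=0, atol=1e-7)

    def test_dead_bands_dropped(self):
        mask = np.array([True, False, True])
        spec = _tiny_spec(3, 2, mask=mask)
        scan = _synthetic_scan(spec, 8)
        cube = compose_cube(scan, _identity_calibration(spec), spec)
        assert cube.n_bands == 2
        np.testing.assert_allclose(
            cube.data, _oracle_cube(spec, 8), rtol=0, atol=1e-7)

    def test_insufficient_frames_rejected(self):
        spec = _tiny_spec(3, 2)
        scan = _synthetic_scan(spec, 8)
        scan.info.n_frames = 5
        scan.frames = scan.frames[:5]
        with pytest.raises(ValueError, match="minimum"):
            compose_cube(scan, _identity_calibration(spec), spec)

    def test_row_count_follows_frame_count(self):
        spec = _tiny_spec(4, 3)
        for n_frames in (8, 9, 13):
            cube = compose_cube(_synthetic_scan(spec, n_frames),
                                _identity_calibration(spec), spec)
            assert cube.data.shape[0] == (n_frames - 4) * 3


class TestSpectralCorrect:
    def _cube(self, wl):
        rng = np.random.default_rng(1)
        return HSCube(data=rng.uniform(0, 1, (4, 5, len(wl))).astype(np.float32),
                      wavelengths_nm=np.asarray(wl, float))

    def test_identity_on_ordered_bands(self):
        cube = self._cube([500.0, 600.0, 700.0])
        calib = CalibrationSet(
            white_frame=np.ones((2, 2)), dark_frame=np.zeros((2, 2)),
            spectral_correction=np.eye(3),
            corrected_wavelengths_nm=cube.wavelengths_nm)
        out = spectral_correct(cube, calib)
        np.testing.assert_allclose(out.data, cube.data, rtol=1e-6)

    def test_permutation_reorders_without_changing_values(self):
        cube = self._cube([700.0, 500.0, 600.0])  # sensor order
        perm = np.array([[0, 1.0, 0], [0, 0, 1.0], [1.0, 0, 0]])
        calib = CalibrationSet(
            white_frame=np.ones((2, 2)), dark_frame=np.zeros((2, 2)),
            spectral_correction=perm,
            corrected_wavelengths_nm=np.array([500.0, 600.0, 700.0]))
        out = spectral_correct(cube, calib)
        np.testing.assert_allclose(out.data[..., 0], cube.data[..., 1], rtol=1e-6)
        np.testing.assert_allclose(out.data[..., 2], cube.data[..., 0], rtol=1e-6)

    def test_dimension_mismatch_rejected(self):
        cube = self._cube([500.0, 600.0])
        calib = CalibrationSet(
            white_frame=np.ones((2, 2)), dark_frame=np.zeros((2, 2)),
            spectral_correction=np.eye(3),
            corrected_wavelengths_nm=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            spectral_correct(cube, calib)


class TestRotateCube:
    def test_four_rotations_are_identity(self):
        rng = np.random.default_rng(2)
        cube = HSCube(data=rng.uniform(0, 1, (5, 7, 3)).astype(np.float32),
                      wavelengths_nm=np.array([1.0, 2.0, 3.0]))
        out = cube
        for _ in range(4):
            out = rotate_cube_ccw(out)
        np.testing.assert_array_equal(out.data, cube.data)

    def test_shape_swaps_spatial_axes(self):
        cube = HSCube(data=np.zeros((5, 7, 3), np.float32),
                      wavelengths_nm=np.array([1.0, 2.0, 3.0]))
        assert rotate_cube_ccw(cube).shape == (7, 5, 3)

    def test_counterclockwise_moves_top_right_to_top_left(self):
        data = np.zeros((4, 6, 1), np.float32)
        data[0, 5, 0] = 1.0
        cube = HSCube(data=data, wavelengths_nm=np.array([500.0]))
        out = rotate_cube_ccw(cube)
        assert out.data[0, 0, 0] == 1.0


class TestEnvi:
    def _cube(self):
        rng = np.random.default_rng(3)
        return HSCube(data=rng.uniform(0, 1, (6, 4, 5)).astype(np.float32),
                      wavelengths_nm=np.linspace(470, 900, 5))

    def test_round_trip_exact(self, tmp_path):
        cube = self._cube()
        write_envi(cube, tmp_path)
        back = read_envi(tmp_path)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.wavelengths_nm, cube.wavelengths_nm)

    def test_header_declares_bsq_and_dimensions(self, tmp_path):
        hdr, bsq = write_envi(self._cube(), tmp_path)
        text = hdr.read_text()
        assert "interleave = bsq" in text
        assert "samples = 4" in text and "lines = 6" in text and "bands = 5" in text
        assert bsq.name == "preprocess.bsq"

    def test_malformed_header_rejected(self, tmp_path):
        write_envi(self._cube(), tmp_path)
        (tmp_path / "preprocess.hdr").write_text("ENVI\nsamples = nope\n")
        with pytest.raises(ValueError, match="malformed|wavelength"):
            read_envi(tmp_path)

    def test_truncated_payload_rejected(self, tmp_path):
        write_envi(self._cube(), tmp_path)
        bsq = tmp_path / "preprocess.bsq"
        bsq.write_bytes(bsq.read_bytes()[:-8])
        with pytest.raises(ValueError, match="payload"):
            read_envi(tmp_path)


class TestPseudoRGB:
    def test_exact_target_bands_selected(self):
        wl = np.array([462.14, 500.0, 543.65, 580.0, 605.61])
        data = np.zeros((2, 2, 5), np.float32)
        for i in range(5):
            data[..., i] = i / 10.0
        cube = HSCube(data=data, wavelengths_nm=wl)
        img = pseudo_rgb(cube)
        # R band index 4, G index 2, B index 0
        assert img[0, 0, 0] == round(0.4 * 255)
        assert img[0, 0, 1] == round(0.2 * 255)
        assert img[0, 0, 2] == 0

    def test_equidistant_tie_prefers_lower_wavelength(self):
        wl = np.array([600.0, 611.22])  # both 5.61 nm from the red target
        data = np.stack([np.full((2, 2), 0.25), np.full((2, 2), 0.75)], axis=-1)
        cube = HSCube(data=data.astype(np.float32), wavelengths_nm=wl)
        img = pseudo_rgb(cube)
        assert img[0, 0, 0] == round(0.25 * 255)

    def test_uniform_white_cube_gives_white_image(self, tmp_path):
        cube = HSCube(data=np.ones((3, 3, 4), np.float32),
                      wavelengths_nm=np.linspace(470, 900, 4))
        img = pseudo_rgb(cube, tmp_path / "pseudo_rgb.tiff")
        assert np.all(img == 255)
        assert (tmp_path / "pseudo_rgb.tiff").exists()


class TestChainEndToEnd:
    @pytest.fixture()
    def raw_scan_path(self, tmp_path, make_microscope, tissue_phantom, small_system):
        mic = make_microscope(tissue_phantom, optics=OpticalConfig.aligned(),
                              noise=NoiseModel(rng_seed=5))
        mic.move_to(x_um=120.0, y_um=120.0, z_um=350.0)
        mag = small_system.magnification(10.0)
        plan = plan_hs_scan(small_system.wedge, mag, 20, mic.pose)
        scan = run_hs_scan(mic, plan, sample_id="chain", mag=mag)
        path = save_raw(scan, tmp_path / "raw_scan")
        calib = reference_calibration(mic, 10.0)
        return path, calib

    def test_full_chain_writes_envi_and_preview(self, raw_scan_path, tmp_path,
                                                small_system):
        path, calib = raw_scan_path
        out = tmp_path / "out"
        cube = preprocess_chain(path, calib, out, small_system.wedge)
        assert (out / "preprocess.hdr").exists()
        assert (out / "preprocess.bsq").exists()
        assert (out / "pseudo_rgb.tiff").exists()
        spec = small_system.wedge
        # rotated: cols x rows x useful bands, transmittance within the clamp
        n_rows = (20 - spec.n_theoretical_bands) * spec.band_height_px
        assert cube.shape == (spec.width_px, n_rows, spec.n_useful_bands)
        assert cube.data.min() >= 0.0 and cube.data.max() <= 1.05
        assert np.all(np.diff(cube.wavelengths_nm) > 0)

    def test_chain_is_deterministic(self, raw_scan_path, tmp_path, small_system):
        path, calib = raw_scan_path
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        preprocess_chain(path, calib, out_a, small_system.wedge)
        preprocess_chain(path, calib, out_b, small_system.wedge)
        for name in ("preprocess.hdr", "preprocess.bsq", "pseudo_rgb.tiff"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()

    def test_white_reference_scan_yields_unit_cube(self, tmp_path, make_microscope,
                                                   tissue_phantom, small_system):
        mic = make_microscope(tissue_phantom)  # noiseless
        mic.move_to(x_um=120.0, y_um=120.0, z_um=350.0)
        mag = small_system.magnification(10.0)
        plan = plan_hs_scan(small_system.wedge, mag, 16, mic.pose)
        scan = run_hs_scan(mic, plan, sample_id="wr", mag=mag, is_white_reference=True)
        path = save_raw(scan, tmp_path / "wr")
        calib = reference_calibration(mic, 10.0)
        cube = preprocess_chain(path, calib, tmp_path / "out", small_system.wedge)
        np.testing.assert_allclose(cube.data, 1.0, atol=1e-6)

    def test_stage_errors_name_the_stage(self, tmp_path, small_system):
        calib = _identity_calibration(small_system.wedge)
        with pytest.raises(RuntimeError, match="decompress"):
            preprocess_chain(tmp_path / "missing.tiff", calib, tmp_path,
                             small_system.wedge)


def test_calibration_set_save_load_round_trip(tmp_path, small_system):
    calib = _identity_calibration(small_system.wedge)
    calib.save(tmp_path / "calib")
    back = CalibrationSet.load(tmp_path / "calib")
    np.testing.assert_allclose(back.white_frame, calib.white_frame)
    np.testing.assert_allclose(back.spectral_correction, calib.spectral_correction)
    np.testing.assert_allclose(back.corrected_wavelengths_nm,
                               calib.corrected_wavelengths_nm)
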