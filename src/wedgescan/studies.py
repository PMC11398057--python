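"""Validation studies: parameter-recovery protocols on the virtual
microscope.

Each function sets up a seeded study at a stated problem size, runs one
part of the acquisition/processing stack against ground truth, and returns
the measured quantities.  They power both the test suite and the
reproduction script (``scripts/acceptance.py``).

The full-band scan study keeps the physical wedge geometry (216 theoretical
bands of 5 rows on a 1088-row sensor, 145 useful) but narrows the sensor
width: the cube's vertical resolution and band count are independent of
width, and a narrow sensor renders in seconds instead of hours.
"""

from __future__ import annotations

import numpy as np

from . import geometry
from .demo import demo_system
from .hs_acquisition import plan_hs_scan, run_hs_scan
from .hs_preprocess import CLIP_EPS, compose_cube, spectral_correct
from .phantom import densest_tissue_position, make_phantom
from .autofocus import autofocus
from .simulator import NoiseModel, OpticalConfig, VirtualMicroscope, reference_calibration
from .specs import AreaSensorSpec, SystemConfig, WedgeSensorSpec

__all__ = [
    "narrowed_full_band_system",
    "minimum_scan_study",
    "autofocus_recovery_study",
    "spectrum_recovery_study",
    "stitching_recovery_study",
]


def narrowed_full_band_system(width_px: int = 24) -> SystemConfig:
    """The physical sensor's full band layout at reduced sensor width."""
    wedge = WedgeSensorSpec(width_px=width_px)
    return SystemConfig(wedge=wedge)


def minimum_scan_study(seed: int, width_px: int = 24,
                       noiseless: bool = False) -> dict:
    """Render a minimum-length (432-frame) wedge scan at 4x on the full
    216-band geometry, run the preprocessing composition, and measure the
    cube dimensions and calibration quality.

    Returns the composed/corrected cube row count, band count, analytic row
    prediction, the clip fraction, and the corrected cube itself.
    """
    system = narrowed_full_band_system(width_px)
    spec = system.wedge
    mag = system.magnification(4.0)
    n_frames = geometry.min_scan_frames(spec)          # 432
    length = geometry.scan_length_um(spec, n_frames, mag)
    fp_um = spec.n_theoretical_bands * spec.band_height_px * spec.pixel_pitch_um / mag.factor
    extent_x = length + fp_um + 200.0
    extent_y = width_px * spec.pixel_pitch_um / mag.factor + 60.0

    phantom = make_phantom(seed % 2**31, extent_um=(extent_x, extent_y),
                           n_classes=3, grid_um=2.0, focus_amplitude_um=0.0,
                           blob_density=2e-4)
    noise = NoiseModel.noiseless() if noiseless else NoiseModel(rng_seed=seed % 2**31)
    mic = VirtualMicroscope(phantom, system, optics=OpticalConfig.aligned(),
                            noise=noise)
    mic.move_to(x_um=extent_x / 2.0, y_um=extent_y / 2.0,
                z_um=mag.working_distance_um)
    plan = plan_hs_scan(spec, mag, n_frames, mic.pose)
    scan = run_hs_scan(mic, plan, sample_id="minimum", mag=mag)
    calib = reference_calibration(mic, mag.factor)
    composed = compose_cube(scan, calib, spec)
    corrected = spectral_correct(composed, calib)
    # same stored-product clamp the preprocessing chain applies
    np.clip(corrected.data, 0.0, 1.0 + CLIP_EPS, out=corrected.data)
    return {
        "n_frames": n_frames,
        "rows": composed.data.shape[0],
        "rows_analytic": geometry.cube_vertical_resolution(spec, n_frames),
        "bands": corrected.n_bands,
        "clip_fraction": composed.clip_fraction,
        "cube": corrected,
        "scan": scan,
        "calibration": calib,
        "system": system,
    }


def autofocus_recovery_study(seed: int, n_runs: int = 20,
                             mag_factor: float = 10.0) -> list[dict]:
    """Autofocus on ``n_runs`` seeded phantoms whose best-focus plane sits a
    random offset (up to ±4 default steps) from the working distance.

    Each run images the densest tissue region, as an operator would.
    Returns per-run records with the true offset, the chosen height, the
    absolute error and the capture count.
    """
    system = demo_system()
    mag = system.magnification(mag_factor)
    fov_x = system.rgb.height_px * system.rgb.pixel_pitch_um / mag.factor
    fov_y = system.rgb.width_px * system.rgb.pixel_pitch_um / mag.factor
    records = []
    for k in range(n_runs):
        run_seed = (seed + k) % 2**31
        rng = np.random.default_rng([run_seed, 99])
        offset = rng.uniform(-4.0 * mag.af_default_step_um,
                             4.0 * mag.af_default_step_um)
        phantom = make_phantom(run_seed, extent_um=(120.0, 120.0), n_classes=3,
                               grid_um=0.5, focus_base_um=offset,
                               focus_amplitude_um=0.0)
        mic = VirtualMicroscope(phantom, system, optics=OpticalConfig(),
                                noise=NoiseModel(rng_seed=run_seed))
        x, y = densest_tissue_position(phantom, (fov_x + 10.0, fov_y + 10.0))
        mic.move_to(x_um=x, y_um=y)
        trace = autofocus(mic, mag)
        records.append({
            "offset_um": offset,
            "chosen_z_um": trace.chosen_z_um,
            "error_um": abs(trace.chosen_z_um - (mag.working_distance_um + offset)),
            "n_captures": trace.n_captures,
        })
    return records


def spectrum_recovery_study(seed: int, n_frames: int = 80,
                            noiseless: bool = True) -> dict:
    """Scan a 3-class phantom, run calibrate → compose → correct, and
    correlate the recovered per-class mean spectra with ground truth
    sampled on the corrected wavelength grid.

    The scan is centered on the densest tissue region so that every class
    contributes enough pixels for a mean spectrum.
    """
    system = demo_system()
    spec = system.wedge
    mag = system.magnification(10.0)
    phantom = make_phantom(seed % 2**31, extent_um=(360.0, 360.0), n_classes=3,
                           grid_um=0.5, focus_amplitude_um=0.0, blob_density=3e-4)
    noise = (NoiseModel.noiseless(quantize=False) if noiseless
             else NoiseModel(rng_seed=seed % 2**31))
    mic = VirtualMicroscope(phantom, system, optics=OpticalConfig.aligned(),
                            noise=noise)
    length = geometry.scan_length_um(spec, n_frames, mag)
    fp_um = spec.n_theoretical_bands * spec.band_height_px * spec.pixel_pitch_um / mag.factor
    x0, y0 = densest_tissue_position(
        phantom, (length + fp_um, spec.width_px * spec.pixel_pitch_um / mag.factor),
        margin_um=10.0)
    mic.move_to(x_um=x0, y_um=y0, z_um=mag.working_distance_um)
    plan = plan_hs_scan(spec, mag, n_frames, mic.pose)
    scan = run_hs_scan(mic, plan, sample_id="spectra", mag=mag)
    calib = reference_calibration(mic, mag.factor)
    cube = spectral_correct(compose_cube(scan, calib, spec), calib)

    # map every cube pixel back to its stage position (ground truth)
    n_th, bh = spec.n_theoretical_bands, spec.band_height_px
    fp = n_th * bh
    p = spec.pixel_pitch_um / mag.factor
    rows = np.arange(cube.data.shape[0])
    strips, offs = np.divmod(rows, bh)
    x = (scan.info.start_xy_um[0] + strips * scan.info.step_um
         + ((n_th - 1) * bh + offs - (fp - 1) / 2.0) * p)
    y = (scan.info.start_xy_um[1]
         - (np.arange(spec.width_px) - (spec.width_px - 1) / 2.0) * p)
    xx = np.broadcast_to(x[:, None], (x.size, y.size))
    yy = np.broadcast_to(y[None, :], (x.size, y.size))
    labels, _ = phantom.sample_fields(xx, yy)
    truth = phantom.transmittance_at(xx, yy, cube.wavelengths_nm)

    correlations = {}
    for c in range(1, phantom.n_classes):
        mask = labels == c
        if mask.sum() < 20:
            continue
        rec = cube.data[mask].mean(axis=0)
        ref = truth[mask].mean(axis=0)
        correlations[c] = float(np.corrcoef(rec, ref)[0, 1])
    return {"correlations": correlations, "cube": cube, "n_frames": n_frames}


def _stitch_system() -> SystemConfig:
    base = demo_system()
    rgb = AreaSensorSpec(width_px=192, height_px=256, pixel_pitch_um=2.4,
                         bit_depth=12)
    return SystemConfig(wedge=base.wedge, rgb=rgb,
                        magnifications=base.magnifications)


def stitching_recovery_study(seed: int, misalignment_deg: float = 0.3,
                             n_cols: int = 3, n_rows: int = 3) -> dict:
    """Whole-slide scan of a densely covered slide with a known camera-mount
    rotation: recover the rotation from the pairwise registrations, stitch,
    and compare both the mosaic and the naive tiling baseline against a
    directly rendered ground-truth field (normalized cross-correlation
    after sub-pixel alignment)."""
    from scipy import ndimage
    from skimage.registration import phase_cross_correlation

    from . import ws_mosaic as wm

    system = _stitch_system()
    rgb = system.rgb
    phantom = make_phantom(seed % 2**31, extent_um=(700.0, 700.0), n_classes=3,
                           grid_um=0.5, focus_amplitude_um=0.0, blob_density=4e-4)
    mag = system.magnification(4.0)
    fov = geometry.field_of_view(rgb, mag)
    origin = (350.0 + n_cols * fov[1] / 4.0, 350.0 + n_rows * fov[0] / 4.0)
    end = (origin[0] - n_cols * fov[1] / 2.0, origin[1] - n_rows * fov[0] / 2.0)
    grid = geometry.tile_grid(origin, end, fov)

    def microscope(mis, noise, vignette=0.15):
        mic = VirtualMicroscope(
            phantom, system,
            optics=OpticalConfig(misalignment_deg=mis, vignette_strength=vignette),
            noise=noise)
        mic.move_to(z_um=mag.working_distance_um)
        return mic

    mic = microscope(misalignment_deg, NoiseModel(rng_seed=seed % 2**31))
    stack = wm.run_ws_scan(mic, grid, mag.factor)
    mosaic = wm.compose_mosaic(stack, seed=seed % 2**31)

    # pairwise mount-rotation recovery from within-row registrations
    tiles = {k: wm.flat_field(v, stack.white_image) for k, v in stack.by_grid().items()}
    angles = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols - 1):
            pair = wm.estimate_pair_affine(tiles[(r, c)], tiles[(r, c + 1)],
                                           "vertical", seed=seed % 2**31)
            angles.append(pair.implied_rotation_deg((rgb.height_px / 2.0, 0.0)))
    # median over pairs: robust to the occasional background-dominated
    # overlap whose registration is keypoint-starved
    recovered_rotation = float(np.median(angles))

    # ground truth: one large render, no vignette, no noise, same rotation
    h, w = rgb.height_px, rgb.width_px
    big = AreaSensorSpec(
        width_px=w + (grid.n_rows - 1) * w // 2,
        height_px=h + (grid.n_cols - 1) * h // 2,
        pixel_pitch_um=rgb.pixel_pitch_um, bit_depth=rgb.bit_depth)
    centers = [grid.stage_position(r, c)
               for r in range(grid.n_rows) for c in range(grid.n_cols)]
    truth_mic = microscope(misalignment_deg, NoiseModel.noiseless(), vignette=0.0)
    truth_mic.move_to(x_um=float(np.mean([p[0] for p in centers])),
                      y_um=float(np.mean([p[1] for p in centers])))
    truth = truth_mic.capture_rgb(mag.factor, sensor=big).astype(float).mean(-1)

    def aligned_ncc(img):
        gray = np.asarray(img, dtype=float)
        gray = gray.mean(-1) if gray.ndim == 3 else gray
        h_c = min(truth.shape[0], gray.shape[0])
        w_c = min(truth.shape[1], gray.shape[1])
        ref = truth[:h_c, :w_c]
        shift, _, _ = phase_cross_correlation(ref, gray[:h_c, :w_c],
                                              upsample_factor=20)
        shifted = ndimage.shift(gray, shift, order=1)[:h_c, :w_c]
        crop = 8
        return wm.ncc(ref[crop:-crop, crop:-crop], shifted[crop:-crop, crop:-crop])

    ncc_stitched = aligned_ncc(mosaic.image)

    baseline_grid = wm.plan_tiling_grid(origin, end, fov)
    baseline_mic = microscope(misalignment_deg, NoiseModel(rng_seed=seed % 2**31))
    baseline_stack = wm.run_ws_scan(baseline_mic, baseline_grid, mag.factor)
    baseline = wm.compose_tiling_baseline(baseline_stack, apply_flat_field=True)
    ncc_baseline = aligned_ncc(baseline)

    return {
        "recovered_rotation_deg": recovered_rotation,
        "true_rotation_deg": misalignment_deg,
        "ncc_stitched": float(ncc_stitched),
        "ncc_baseline": float(ncc_baseline),
        "n_fallback_pairs": len(mosaic.composition_log),
        "grid": (grid.n_cols, grid.n_rows),
    }
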