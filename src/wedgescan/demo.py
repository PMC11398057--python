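"""End-to-end demonstration at reduced scale.

``run_demo`` drives the full acquisition methodology on a seeded phantom
with a scaled-down virtual instrument: whole-slide scan → stitching →
fixture ROI labels → automatic HS + RGB capture sequence → preprocessing
chain, writing every artifact and a checksummed manifest so that two runs
with the same seed are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from . import geometry, hs_preprocess, labels as labels_mod, ws_mosaic
from .phantom import make_phantom
from .simulator import NoiseModel, OpticalConfig, VirtualMicroscope, reference_calibration
from .specs import (
    AreaSensorSpec,
    MagnificationSpec,
    SystemConfig,
    WedgeSensorSpec,
)

__all__ = ["demo_system", "run_demo"]


def demo_system() -> SystemConfig:
    """A reduced instrument that keeps every geometric relation of the full
    system (90° camera rotation, band wedge, half-overlap grids) but renders
    in seconds: an 8-band wedge sensor and a 96×72 RGB sensor."""
    wedge = WedgeSensorSpec(
        width_px=48, height_px=32, band_height_px=4,
        n_theoretical_bands=8, n_useful_bands=6,
        pixel_pitch_um=5.5, bit_depth=10,
    )
    rgb = AreaSensorSpec(width_px=72, height_px=96, pixel_pitch_um=2.4, bit_depth=12)
    mags = {
        4.0: MagnificationSpec(4.0, 470.0, 10.0),
        10.0: MagnificationSpec(10.0, 350.0, 5.0),
    }
    return SystemConfig(wedge=wedge, rgb=rgb, magnifications=mags)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_demo(seed: int, out_dir: str | Path,
             system: SystemConfig | None = None) -> dict:
    """Run the full methodology once; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    system = system if system is not None else demo_system()

    phantom = make_phantom(seed, extent_um=(240.0, 240.0), n_classes=3,
                           grid_um=0.5, focus_amplitude_um=4.0)
    phantom.save(out / "phantom.npz")
    mic = VirtualMicroscope(
        phantom, system,
        optics=OpticalConfig(misalignment_deg=0.3),
        noise=NoiseModel(rng_seed=seed),
    )

    # -- whole-slide scan at 4x over an operator-style overview region -----
    ws_mag = 4.0
    overview = geometry.OverviewImageFrame(
        width_px=120, height_px=120,
        top_left_stage_um=(220.0, 220.0), bottom_right_stage_um=(20.0, 20.0),
    )
    origin = geometry.region_to_stage(overview, 30, 40)
    end = geometry.region_to_stage(overview, 30 + 36, 40 + 26)
    fov = geometry.field_of_view(system.rgb, system.magnification(ws_mag))
    grid = geometry.tile_grid(origin, end, fov)

    mic.move_to(z_um=system.magnification(ws_mag).working_distance_um)
    stack = ws_mosaic.run_ws_scan(mic, grid, ws_mag)
    mosaic = ws_mosaic.compose_mosaic(stack, seed=seed)
    mosaic_path = out / "mosaic.tiff"
    tifffile.imwrite(mosaic_path, np.clip(mosaic.image, 0, system.rgb.max_value
                                          ).astype(np.uint16))
    ws_info = labels_mod.make_ws_info(grid, ws_mag, system.rgb)
    (out / "ws_scan_info.json").write_text(json.dumps(ws_info, indent=2))

    # -- fixture labels centered on two interior tiles ---------------------
    fixture = []
    for i, (r, c) in enumerate([(1, 1), (2, 1)], start=1):
        target = grid.stage_position(r, c)
        cx, cy = geometry.stage_to_roi_center(grid.origin_um, target, system.rgb, ws_mag)
        fixture.append(labels_mod.ROILabel(
            top_left_px=(cx - 3.0, cy - 3.0), width_px=6.0, height_px=6.0,
            histology_class="tumor", index=i, ws_magnification=ws_mag,
        ))
    labels_path = out / "labels.json"
    labels_mod.write_labels(fixture, labels_path)

    # -- automatic capture sequence at 10x ---------------------------------
    seq_mag = 10.0
    tasks = labels_mod.plan_sequence(fixture, ws_info, seq_mag,
                                     system.rgb, system.wedge)
    manifests = labels_mod.run_sequence(mic, tasks, out)

    # -- preprocessing chain on every raw scan -----------------------------
    calib = reference_calibration(mic, seq_mag)
    calib.save(out / "calibration")
    cubes = []
    for m in manifests:
        if m.get("status") != "ok":
            continue
        cube = hs_preprocess.preprocess_chain(
            out / m["raw_scan"], calib, out / m["folder"], system.wedge)
        cubes.append({"folder": m["folder"], "shape": list(cube.shape)})

    files = sorted(p for p in out.rglob("*") if p.is_file())
    manifest = {
        "seed": seed,
        "grid": {"n_cols": grid.n_cols, "n_rows": grid.n_rows, "n_total": grid.n_total},
        "mosaic_shape": list(mosaic.image.shape),
        "tasks": manifests,
        "cubes": cubes,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "demo_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
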