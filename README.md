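# wedgescan

A hardware-free re-creation of the acquisition and processing software of a
combined RGB + wedge-linescan **hyperspectral microscope** for digital
pathology — the class of instrument that scans histological slides with
both a conventional color camera and a spectral camera, so that every pixel
of a region of interest carries a transmittance spectrum instead of three
color values.

The package implements the full software stack of such an instrument:

* **Scan geometry** — fields of view, the per-frame stage step of a wedge
  scan `d = FOVv·Bh/h`, the minimum frame count `2·n_bands`, cube sizing
  `Rv = (Nf − n_bands)·Bh`, overview↔stage coordinate maps, half-overlap
  tile grids, and the ROI-center conversion
  `X = Ox − (ROIx + ROIw/2 − H/2)·M·Px` of the automatic sequence.
* **Passive autofocus** — variance-of-Laplacian scoring with a
  mountain-climbing search (±2-step direction probes, half-step climb,
  15-capture cap, argmax).
* **Hyperspectral scanning** — stage trajectory planning, frame capture,
  and bit-exact lossless persistence of the raw wedge-frame stack.
* **Preprocessing chain** — radiometric calibration `T = (R−DC)/(WR−DC)`,
  band-by-band cube composition, spectral correction (band reordering +
  crosstalk unmixing), 90° rotation, ENVI (`.hdr`/`.bsq`) output and a
  pseudo-RGB preview.
* **Whole-slide mosaicking** — snake-order half-overlap acquisition,
  flat-field correction, SIFT + brute-force matching + robust affine
  registration, row-then-global composition, and a naive tiling baseline.
* **ROI label schema and the automatic capture sequence** — move →
  autofocus → RGB snapshot → HS scan per labeled region.

Because there is no camera or stage attached, the package ships a
**virtual microscope**: a seeded, deterministic optical simulator that
renders RGB and wedge frames from a synthetic tissue phantom with known
class spectra, focus relief, mount misalignment, vignetting, band
crosstalk and sensor noise. Every algorithm is validated by *parameter
recovery* against that ground truth — recovered spectra vs. true spectra,
chosen focus vs. true focus surface, recovered mount rotation vs. the
configured misalignment, and so on. See `docs/methods.md` for the models
and their assumptions.

## Worked example

The deterministic scan arithmetic of the physical instrument
(2048×1088 wedge sensor, 5-px bands, 216 theoretical bands; 5472×3648 RGB
sensor at 2.4 μm pitch):

```python
>>> import wedgescan as ws
>>> system = ws.default_system()
>>> ws.step_distance(system.wedge, system.magnification(10.0))
2.75
>>> ws.min_scan_frames(system.wedge)
432
>>> ws.cube_vertical_resolution(system.wedge, 432)
1080
>>> fov = ws.field_of_view(system.rgb, system.magnification(4.0))
>>> fov
(3283.2, 2188.7999999999997)
>>> grid = ws.tile_grid((40000.0, 30000.0), (20000.0, 18000.0), fov)
>>> grid.n_cols, grid.n_rows, grid.n_total
(19, 8, 152)
```

Reading: at 10× the stage advances 2.75 μm between wedge frames; a
full-coverage scan needs 432 frames and composes into a cube with 1080
spatial rows; a 20 × 12 mm whole-slide region at 4× becomes a 19 × 8 grid
of 152 half-overlapping RGB tiles.

The whole methodology end to end — phantom → whole-slide scan → stitching
→ fixture labels → automatic HS+RGB sequence → preprocessing — runs at
reduced scale from the command line:

```bash
$ wedgescan demo --seed 7 --out demo_out
demo seed=7: 23 files -> demo_out
```

`demo_out/` then contains the stitched `mosaic.tiff` (a 3×3 tile grid),
`labels.json`, and per-ROI folders `tumor_1/`, `tumor_2/` each holding the
RGB snapshot, the lossless raw scan, the preprocessed ENVI cube
(`preprocess.hdr`/`preprocess.bsq`, here 48×32 px × 6 bands at demo scale)
and `pseudo_rgb.tiff`, plus a checksummed `demo_manifest.json` — two runs
with the same seed produce byte-identical artifacts. Individual steps are
also exposed (`wedgescan autofocus`, `hs-scan`, `ws-scan`, `stitch`,
`preprocess`, `plan-sequence`, `run-sequence`; see `--help`).

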