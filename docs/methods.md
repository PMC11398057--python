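# Methods

`wedgescan` re-creates, in software, the acquisition and processing stack of
a combined RGB + wedge-linescan hyperspectral (HS) brightfield microscope:
scan geometry, passive autofocus, HS scanning and cube preprocessing,
whole-slide (WS) mosaicking, and ROI-driven automatic capture sequences.
Because the package is hardware-free, every algorithm is exercised against a
built-in virtual microscope whose ground truth is known exactly, so
correctness is established by parameter recovery rather than by comparison
with a physical instrument.

## Instrument model

The modeled instrument carries two cameras behind one trinocular tube
(80% of the lamp light to the HS path, 20% to the RGB path), three
objectives (4×/10×/40×, working distances 470/350/340 μm), a motorized XY
stage (0.02 μm/step) and a Z drive (0.1 μm/step). Both cameras are mounted
rotated 90° with respect to the stage: image rows run along stage X and
image columns along stage Y, with the pixel index increasing as the stage
coordinate decreases. All commanded stage moves snap to the nearest integer
multiple of the axis resolution.

The HS camera is a wedge-linescan sensor: 2048×1088 px, 5.5 μm pitch,
10-bit, covered by 216 spectral filter stripes ("bands") of 5 rows each
spanning 470–900 nm, of which 145 carry signal (the dead-band positions are
manufacturer-specific and are a configuration input; the default masks the
sensor edges). The 8 sensor rows left over by the 216×5 tiling are ignored.
The RGB camera is a 5472×3648 px, 2.4 μm pitch area sensor.

### Scan geometry

With magnification M and pixel pitch `p`, the field of view per axis is
`n_px · p / M`. Three quantities govern a wedge scan:

* per-frame stage step `d = FOVv · Bh / h = Bh · p / M`
  (6.875 / 2.75 / 0.6875 μm at 4×/10×/40×),
* minimum frame count `Nf,min = 2 · n_bands` (= 432),
* cube vertical resolution `Rv = (Nf − n_bands) · Bh`
  (432 frames → 1080 rows).

`Rv` above is the convention that simultaneously reproduces the two anchor
values this instrument class is designed around — a minimum scan of
`2·n_bands` frames and a 1080-row minimum cube — and it is validated
against a brute-force coverage oracle that exhaustively tracks which scene
strip each band of each frame observes. Of
the `Nf − n_bands + 1` strips that are seen by every band, the composer
drops the last one, which is only completed by the final frame — this
convention is what matches the anchors.

Wedge band index counts from the *trailing* sensor edge with respect to the
scan axis (band `b` occupies row block `n_bands − 1 − b`), and the HS
camera's row axis runs against stage X. Under these two conventions a scan
stepped by `d` satisfies the composition rule "cube strip `s`, band `b` ←
frame `s + b`" exactly, and cube rows map linearly and ascending onto the
scene (verified numerically to float32 rounding, ≤ 2·10⁻⁸, at zero noise).

Operator-facing coordinate maps: overview-image pixels map to stage μm by
the corner-anchored affine `O = (TL − BR)(1 − R/dim) + BR` per axis (an
exact bijection, inverse recovered to < 0.5 px); WS tile grids divide the
selected region into `Nc = ⌈span_x / (FOVv/2)⌉` columns and
`Nr = ⌈span_y / (FOVh/2)⌉` rows (ceiling, so the region is always fully
covered; note the axis swap from the 90° camera rotation), visited in a
snake order; ROI centers convert to stage targets by
`X = Ox − (ROIx + ROIw/2 − H/2)·M·Px` (and symmetrically for Y with W).
ROI pixel coordinates refer to a reduced-resolution WS view whose pixel
size on the sample is `M·Px` μm — the scale at which that conversion is
exact — and the simulator round trip verifies the centering.

## Virtual microscope

### Phantom (ground truth)

A phantom is a flat slide sampled on a grid (default 0.5–2 μm, chosen to
resolve the finest camera pixel in use) carrying:

* a tissue-class label map: elliptical nucleus-like blobs and sinuous
  ridge-like vessels over empty background (default ≈ two-thirds tissue
  coverage; the WS stitching studies use a denser slide, `blob_density`
  4·10⁻⁴ μm⁻², the regime WS scans target);
* per-class smooth absorbance spectra — three-component Gaussian mixtures
  on a 450–950 nm grid, resampled deterministically until mutually
  separated in L2 — with transmittance following Beer–Lambert,
  `T = 10^(−A_c(λ)·texture)`, background exactly 1;
* a multiplicative optical-density texture with three spatial scales
  (coarse ≈ 12 μm, fine ≈ 1.6 μm, speckle ≈ 1 μm). The finest scale is
  what gives tissue interiors the high spatial frequency that Laplacian
  focus scoring and SIFT keypoint detection rely on; without it,
  blob-interior fields are nearly flat and both legitimately fail;
* a smooth best-focus relief z*(x, y) expressed relative to the objective's
  working distance (a parfocal instrument; default amplitude 8 μm,
  emulating the micrometric surface variation of real sections).

Everything is deterministic per seed.

### Rendering

Captures sample the phantom on the sensor grid mapped through the
90°-rotated mount plus a configurable rotation misalignment (default 0.3°,
the few-tenths-of-a-degree error of a manually adjusted mount). The optical
envelope is a halogen-like illumination spectrum (flat above ~500 nm), an
objective transmittance of 95% in the visible declining to 50% at 1000 nm,
a radial vignette (strength 0.15), and defocus blur with Gaussian kernel
radius `0.1 μm per μm` of |z − z*| (a depth of field of a few μm; blur is
capped at σ = 25 px far from focus). Spatially varying defocus is rendered
by blending four blur levels per pixel, which is what lets a high fold
defocus differently from the tissue around it. Wedge frames integrate each
band's strip against its wavelength with a tridiagonal neighbor-band
crosstalk (per-neighbor leak 0.05, rows summing to 1); dead bands read
baseline. Sensor noise is signal-dependent shot noise (scale 0.3 DN^1/2,
SNR ≈ 100 at white level, typical of a decent machine-vision CMOS) plus
2 DN-class read noise, then quantization to 10 bits (HS) or 12 bits (RGB).
Setting the noise scales to zero gives bit-reproducible renders;
`quantize=False` additionally skips rounding for exact algebraic checks.

The exact spectral-correction matrix is derived from the ground truth: a
white-normalized pixel spectrum over the useful bands satisfies
`t = D⁻¹ C W T` (C crosstalk, W = diag of illumination weights,
D = diag(C·w)), so the correction is `M = P·W⁻¹·C⁻¹·D` with P the
ascending-wavelength permutation — the stand-in for the matrix a camera
manufacturer would ship.

What the phantom does *not* emulate: per-pixel quantum-efficiency
variation, wavelength-dependent PSFs, chromatic aberration, stage
vibration, section-thickness variation, and real histological spectra.
Passing recovery tests therefore demonstrates the correctness of the
*algorithms and their bookkeeping* (geometry, calibration algebra,
registration, sequencing) under controlled optics, not clinical
performance on real tissue.

## Autofocus

Sharpness is the variance of a 3×3 Laplacian of the grayscale capture. The
search starts at the objective's working distance, probes ±2 default steps
(10/5/1 μm per objective), and compares the two probe scores against each
other: an exact tie (a featureless field) leaves Z at the initial position;
otherwise the stage climbs from the *initial* height toward the better
probe in half-steps for 15 captures and returns the argmax over everything
evaluated (≤ 18 renders total; probes do not count toward the cap).
Two details matter:

* the climb runs to the cap instead of halting at the first score drop —
  far from focus the score is a noise plateau on which a single drop is
  meaningless, and the cap-then-argmax rule is what suppresses false
  positives;
* climbing from the initial height makes the reachable grid
  `z₀ + k·step/2`, whose nearest point is within a quarter step of any
  true optimum in range — the accuracy the recovery study checks.

Recovery study: 20 phantoms with focus offsets drawn uniformly within ±4
default steps, each imaged at its densest tissue region (an operator
focuses on tissue, not empty glass); the chosen height lands within
step/4 of the truth in ≥ 18/20 runs. The documented failure mode — a
small, high-contrast fold at a different height capturing the focus — is
reproduced as a test, not treated as a bug.

## HS acquisition and preprocessing

A scan plan places `Nf` poses a step `d` apart, starting half the scan
length before the region center; the driver captures one frame per pose,
restores the stage, and persists the stack through a pluggable lossless
codec (default: multi-page grayscale TIFF with zlib/deflate; 10-bit frames
in 16-bit little-endian words; any bit-exact multi-frame container
qualifies; achieved compression is logged, never asserted). Folder layout
`<sample_id>/data/<magnification>/` plus a JSON scan-info record.

Preprocessing: decompress → radiometric calibration
`T = (R − DC)/(WR − DC)` per frame (white = empty-slide capture, dark =
covered path; pixels with `WR − DC ≤ 0` are flagged invalid; white/dark are
single frames per magnification, broadcast) → band-by-band composition
(above) → spectral correction (reorder + unmix) → 90° CCW rotation (before
pseudo-RGB, matching the stage order) → ENVI output (`preprocess.hdr` /
`preprocess.bsq`, BSQ interleave, 32-bit float, wavelengths at full
precision) and an 8-bit `pseudo_rgb.tiff` built from the bands nearest
605.61 / 543.65 / 462.14 nm (equidistant ties resolve to the lower
wavelength; out-of-range targets use the nearest edge band with a warning).
Transmittance is clamped to [0, 1.05] before storage — the 0.05 headroom
tolerates noise around the background level T = 1 — and the fraction of
values lost to the clamp is logged (< 1% at default noise; ~0.05% in the
minimum-scan study).

## Whole-slide mosaicking

Tiles are captured on the half-overlap snake grid and flat-field corrected
by division with the empty-slide white image. Pairwise registration of the
overlapping halves: SIFT keypoints (images normalized to [0, 1]; DoG
threshold 0.005), exhaustive matching keeping mutual best matches, RANSAC
consensus on a *rigid* model (2-point samples, 3 px residual) — a 3-point
affine consensus hallucinates on sparse speckle matches — followed by a
least-squares affine refit on the inliers with the scale constrained to
[0.98, 1.02]. Three regularizations reflect the physics:

* same-mount captures cannot rotate relative to each other, so a linear
  part within 10⁻² of the identity is projected onto it (keeping the
  displacement it implied at the patch centroid);
* the translation is refined to sub-pixel by direct SSD minimization over
  the overlap halves (cubic-spline interpolation, Nelder–Mead seeded by
  the keypoint fit). Fourier phase correlation was evaluated first and
  shows a systematic ~0.1 px bias on this texture (checked against
  brute-force SSD), which alone would exceed the rotation-recovery
  tolerance; SSD matching is unbiased at the ±0.05 px level;
* a fit deviating more than 16 px or 2° from the nominal grid step is a
  spurious consensus on repetitive texture and falls back to nominal
  placement (logged).

Rows are composed by chaining the within-row transforms; composed row
strips are registered to each other the same way; the canvas is assembled
with last-written-wins blending feathered over a 16 px band (weights in
power-of-two steps, so blending identical content is bit-exact, and a
noiseless, misalignment-free pipeline reproduces the directly rendered
field *exactly* — near-integer translations snap to integers and paste
without interpolation). Both the nominal canvas (`Nc·H × Nr·W`) and the
actually covered extent are reported.

Because all captures share the camera orientation, the mount rotation
appears as the angle between each measured pairwise translation and the
nominal grid step; the recovered rotation is the median of that angle over
the within-row pairs (robust to an occasional background-dominated
overlap). Recovery study (3×3 grid, 256×192 px tiles, 0.3° truth, default
noise): rotation recovered within 0.001–0.044° over 8 seeds; stitched
mosaic NCC against the directly rendered ground-truth field 0.987–0.990
(after sub-pixel alignment of the two canvases), strictly above the naive
no-overlap tiling baseline (0.973–0.981) in every case.

## Labels and the automatic sequence

Labels are JSON records (top-left px, width, height, histology class,
per-class index, WS magnification); unknown fields are preserved. Planning
converts each ROI center to a stage target (skipping, with a warning,
labels outside the WS view bounds) and assigns the minimum frame count.
The sequence then, per label: move → autofocus → RGB snapshot → HS scan,
into `<histology>_<index>/` with a per-task manifest; a failing task is
recorded and isolated. Manifest paths are stored relative to the work
directory so same-seed runs are byte-identical.

## Problem sizes and reduced instruments

Geometry operations always use the full sensor specification — they are
closed-form arithmetic. Simulation studies choose sizes that keep full
fidelity where it matters:

* *minimum-scan study*: the real band layout (216 bands × 5 px on 1088
  rows, 432 frames) at sensor width 24 px — cube rows and band counts are
  independent of width;
* *demo instrument*: 8-band wedge (6 useful, band height 4 px so the scan
  step is an exact multiple of the 0.02 μm stage resolution at 4× and
  10×) and a 96×72 RGB sensor;
* *stitching studies*: a 192×256 px RGB sensor — large enough for dense
  keypoints and 0.05°-level angle resolution over a 128 px baseline.

## Known limitations

* The rotation misalignment is recovered from translation drift, not from
  relative rotations (which are zero by construction between same-mount
  captures); instruments with per-capture rotation jitter would need the
  unconstrained affine path.
* The crosstalk model is tridiagonal and its exact inverse is available to
  the correction step; a real camera's correction matrix is only
  approximately known, so real spectra would carry residual mixing.
* Renders interpolate the phantom bilinearly (labels nearest-neighbor),
  so sub-pixel registration against ground truth carries a small
  resampling noise floor (±0.05 px) visible in the rotation-recovery
  spread.
* The naive tiling baseline shares the stitched pipeline's flat-field
  correction; it differs only in geometry, which is the comparison of
  interest.
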