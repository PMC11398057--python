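"""Preprocessing chain: raw wedge frames → calibrated hyperspectral cube.

Stages, in order: decompress the raw container, radiometrically calibrate
each frame against white/dark references (T = (R − DC)/(WR − DC)), compose
the cube band-by-band (each cube strip gathers one band block from each of
``n_bands`` consecutive frames), apply the spectral-correction matrix
(band reordering to ascending wavelength + crosstalk unmixing), rotate the
cube 90° counterclockwise to restore sample orientation, and write ENVI
files (``preprocess.hdr`` / ``preprocess.bsq``) plus a ``pseudo_rgb.tiff``
preview built from the bands nearest 605.61 / 543.65 / 462.14 nm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import geometry
from .hs_acquisition import LosslessCodec, RawHSScan, ScanInfoRecord, load_raw
from .specs import WedgeSensorSpec

__all__ = [
    "CalibrationSet",
    "HSCube",
    "calibrate_frame",
    "compose_cube",
    "spectral_correct",
    "rotate_cube_ccw",
    "write_envi",
    "read_envi",
    "pseudo_rgb",
    "preprocess_chain",
]

log = logging.getLogger(__name__)

CLIP_EPS = 0.05
PSEUDO_RGB_TARGETS_NM = (605.61, 543.65, 462.14)  # R, G, B


@dataclass
class CalibrationSet:
    """White/dark reference frames plus the spectral-correction matrix.

    ``spectral_correction`` maps the composed cube's useful bands (sensor
    order) to corrected bands ordered by ascending wavelength
    (``corrected_wavelengths_nm``); for the virtual instrument it is built
    from the known crosstalk and illumination (see
    ``wedgescan.simulator.reference_calibration``).
    """

    white_frame: np.ndarray
    dark_frame: np.ndarray
    spectral_correction: np.ndarray         # (n_out, n_useful)
    corrected_wavelengths_nm: np.ndarray    # (n_out,) strictly ascending

    def __post_init__(self) -> None:
        self.white_frame = np.asarray(self.white_frame, dtype=float)
        self.dark_frame = np.asarray(self.dark_frame, dtype=float)
        self.spectral_correction = np.asarray(self.spectral_correction, dtype=float)
        self.corrected_wavelengths_nm = np.asarray(self.corrected_wavelengths_nm, dtype=float)
        if self.white_frame.shape != self.dark_frame.shape:
            raise ValueError("white and dark reference frames must share a shape")
        if self.spectral_correction.shape[0] != self.corrected_wavelengths_nm.size:
            raise ValueError("one corrected wavelength per output band required")
        if np.any(np.diff(self.corrected_wavelengths_nm) <= 0):
            raise ValueError("corrected wavelengths must be strictly ascending")

    def save(self, directory: str | Path) -> None:
        """Write references (TIFF), the correction matrix (CSV) and a JSON
        descriptor into ``directory``."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(d / "white_frame.tiff", self.white_frame.astype(np.float32))
        tifffile.imwrite(d / "dark_frame.tiff", self.dark_frame.astype(np.float32))
        np.savetxt(d / "spectral_correction.csv", self.spectral_correction, delimiter=",")
        (d / "calibration.json").write_text(json.dumps({
            "white_frame": "white_frame.tiff",
            "dark_frame": "dark_frame.tiff",
            "spectral_correction": "spectral_correction.csv",
            "corrected_wavelengths_nm": self.corrected_wavelengths_nm.tolist(),
        }, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "CalibrationSet":
        d = Path(directory)
        desc = json.loads((d / "calibration.json").read_text())
        matrix = np.loadtxt(d / desc["spectral_correction"], delimiter=",", ndmin=2)
        return cls(
            white_frame=tifffile.imread(d / desc["white_frame"]),
            dark_frame=tifffile.imread(d / desc["dark_frame"]),
            spectral_correction=matrix,
            corrected_wavelengths_nm=np.asarray(desc["corrected_wavelengths_nm"]),
        )


@dataclass
class HSCube:
    """rows × cols × bands transmittance cube with ascending wavelengths."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    provenance: ScanInfoRecord | None = None
    clip_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.wavelengths_nm.size:
            raise ValueError("one wavelength per band required")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def calibrate_frame(raw: np.ndarray, white: np.ndarray, dark: np.ndarray,
                    return_valid: bool = False):
    """Radiometric calibration T = (R − DC) / (WR − DC), elementwise.

    Pixels where WR − DC ≤ 0 carry no calibration information; they are
    flagged invalid and set to 0.
    """
    raw = np.asarray(raw, dtype=float)
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if raw.shape != white.shape or raw.shape != dark.shape:
        raise ValueError("raw, white and dark frames must share a shape")
    denom = white - dark
    valid = denom > 0
    t = np.zeros_like(raw)
    np.divide(raw - dark, denom, out=t, where=valid)
    if return_valid:
        return t, valid
    return t


def compose_cube(scan: RawHSScan, calib: CalibrationSet,
                 spec: WedgeSensorSpec) -> HSCube:
    """Calibrate every frame and place each band block at its final cube
    position (uncorrected band order).

    Cube strip ``s`` of band ``b`` is the band-``b`` row block of frame
    ``s + b``; with ``Nf`` frames the cube has ``(Nf − n_bands) × Bh`` rows.
    Dead bands are dropped per the useful-band mask.  Transmittance is
    clipped to [0, 1 + 0.05]; the fraction of values lost to the clamp is
    recorded and logged.
    """
    n_min = geometry.min_scan_frames(spec)
    if scan.n_frames < n_min:
        raise ValueError(f"scan has {scan.n_frames} frames; minimum is {n_min}")
    n_th, bh = spec.n_theoretical_bands, spec.band_height_px
    n_strips = scan.n_frames - n_th
    rows = n_strips * bh
    useful = spec.useful_indices
    cube = np.empty((rows, spec.width_px, useful.size), dtype=np.float32)
    frames = scan.frames
    wr, dc = calib.white_frame, calib.dark_frame
    for u, t in enumerate(useful):
        band_rows = spec.band_rows(int(t))
        block = frames[int(t): int(t) + n_strips, band_rows, :].astype(float)
        t_cal = calibrate_frame(
            block,
            np.broadcast_to(wr[band_rows], block.shape),
            np.broadcast_to(dc[band_rows], block.shape),
        )
        cube[:, :, u] = t_cal.reshape(rows, spec.width_px)
    clipped = float(np.mean((cube < 0.0) | (cube > 1.0 + CLIP_EPS)))
    np.clip(cube, 0.0, 1.0 + CLIP_EPS, out=cube)
    if clipped > 0:
        log.info("compose_cube: %.3f%% of transmittance values clipped to "
                 "[0, %.2f]", 100 * clipped, 1.0 + CLIP_EPS)
    return HSCube(
        data=cube,
        wavelengths_nm=spec.band_wavelengths_nm[useful],
        provenance=scan.info,
        clip_fraction=clipped,
    )


def spectral_correct(cube: HSCube, calib: CalibrationSet) -> HSCube:
    """Multiply each pixel spectrum by the correction matrix: unmixes the
    neighbor-band crosstalk and reorders bands to ascending wavelength."""
    m = calib.spectral_correction
    if m.shape[1] != cube.n_bands:
        raise ValueError(
            f"correction matrix expects {m.shape[1]} input bands, cube has {cube.n_bands}"
        )
    data = cube.data @ m.T
    return HSCube(
        data=data.astype(np.float32),
        wavelengths_nm=calib.corrected_wavelengths_nm,
        provenance=cube.provenance,
        clip_fraction=cube.clip_fraction,
    )


def rotate_cube_ccw(cube: HSCube) -> HSCube:
    """Rotate every band image 90° counterclockwise (spatial axes only);
    four applications are the identity."""
    return HSCube(
        data=np.rot90(cube.data, k=1, axes=(0, 1)).copy(),
        wavelengths_nm=cube.wavelengths_nm,
        provenance=cube.provenance,
        clip_fraction=cube.clip_fraction,
    )


# -- ENVI I/O ---------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16, 1: np.uint8}


def write_envi(cube: HSCube, directory: str | Path, stem: str = "preprocess"
               ) -> tuple[Path, Path]:
    """Write ``<stem>.hdr`` + ``<stem>.bsq`` (band-sequential, 32-bit float,
    little endian) with the wavelength list at full precision."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    hdr_path = d / f"{stem}.hdr"
    bsq_path = d / f"{stem}.bsq"
    rows, cols, bands = cube.shape
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths_nm)
    hdr_path.write_text(
        "ENVI\n"
        "description = {wedgescan preprocessed transmittance cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    np.ascontiguousarray(cube.data.astype("<f4").transpose(2, 0, 1)).tofile(bsq_path)
    return hdr_path, bsq_path


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for line in text.splitlines()[1:]:
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            buf = [value]
            in_braces = True
        else:
            fields[key] = value
    return fields


def read_envi(directory: str | Path, stem: str = "preprocess") -> HSCube:
    """Read a cube written by :func:`write_envi`; raises ``ValueError`` on a
    malformed header."""
    d = Path(directory)
    hdr = _parse_envi_header((d / f"{stem}.hdr").read_text())
    try:
        rows = int(hdr["lines"])
        cols = int(hdr["samples"])
        bands = int(hdr["bands"])
        dtype_code = int(hdr["data type"])
        interleave = hdr["interleave"].lower()
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed ENVI header: {exc}") from exc
    if interleave != "bsq":
        raise ValueError(f"unsupported interleave {interleave!r} (expected bsq)")
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    wl_text = hdr.get("wavelength", "{}").strip().strip("{}")
    wavelengths = np.array([float(v) for v in wl_text.split(",") if v.strip()])
    if wavelengths.size != bands:
        raise ValueError("wavelength list length does not match band count")
    data = np.fromfile(d / f"{stem}.bsq", dtype=_ENVI_DTYPES[dtype_code])
    if data.size != rows * cols * bands:
        raise ValueError("BSQ payload size does not match header dimensions")
    data = data.reshape(bands, rows, cols).transpose(1, 2, 0)
    return HSCube(data=data, wavelengths_nm=wavelengths)


def pseudo_rgb(cube: HSCube, path: str | Path | None = None,
               targets_nm: tuple[float, float, float] = PSEUDO_RGB_TARGETS_NM
               ) -> np.ndarray:
    """8-bit color preview from the three bands nearest the canonical
    R/G/B wavelengths (equidistant ties resolve to the lower wavelength;
    out-of-range targets use the nearest edge band, with a warning)."""
    wl = cube.wavelengths_nm
    if np.any(np.diff(wl) <= 0):
        raise ValueError("cube wavelengths must be ascending")
    channels = []
    for target in targets_nm:
        if target < wl[0] or target > wl[-1]:
            log.warning("pseudo-RGB target %.2f nm outside cube range "
                        "[%.2f, %.2f]; using nearest edge band", target, wl[0], wl[-1])
        idx = int(np.argmin(np.abs(wl - target)))  # first minimum = lower wavelength
        channels.append(cube.data[:, :, idx])
    img = np.stack(channels, axis=-1)
    img = np.clip(img, 0.0, 1.0)
    img8 = np.rint(img * 255.0).astype(np.uint8)
    if path is not None:
        tifffile.imwrite(Path(path), img8, photometric="rgb")
    return img8


def preprocess_chain(raw_path: str | Path, calib: CalibrationSet,
                     out_dir: str | Path, spec: WedgeSensorSpec,
                     codec: LosslessCodec | None = None) -> HSCube:
    """Full chain on a stored raw scan: decompress → calibrate+compose →
    spectral-correct → rotate 90° CCW → write ENVI + pseudo-RGB.

    Deterministic and idempotent: re-running on the same input rewrites
    byte-identical outputs.  Errors carry the failing stage name.
    """
    out = Path(out_dir)
    def _clamp(cube: HSCube) -> HSCube:
        # unmixing can push noisy values slightly past the compose clamp
        np.clip(cube.data, 0.0, 1.0 + CLIP_EPS, out=cube.data)
        return cube

    stages = [
        ("decompress", lambda _: load_raw(raw_path, codec=codec)),
        ("compose", lambda scan: compose_cube(scan, calib, spec)),
        ("spectral_correction", lambda cube: _clamp(spectral_correct(cube, calib))),
        ("rotation", rotate_cube_ccw),
        ("envi_write", lambda cube: (write_envi(cube, out), cube)[1]),
        ("pseudo_rgb", lambda cube: (pseudo_rgb(cube, out / "pseudo_rgb.tiff"), cube)[1]),
    ]
    value: object = None
    for name, fn in stages:
        try:
            value = fn(value)
        except Exception as exc:
            raise RuntimeError(f"preprocess stage '{name}' failed: {exc}") from exc
    return value
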