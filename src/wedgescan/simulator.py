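"""Virtual microscope: deterministic optical rendering from a phantom.

The :class:`VirtualMicroscope` stands in for the real instrument.  It keeps
a stage pose and renders what either camera would see: RGB area captures
(with defocus blur, vignetting, a small camera-to-stage rotation
misalignment, shot/read noise and quantization) and single wedge-linescan
hyperspectral frames (per-band spectral sampling with neighbor-band
crosstalk and the halogen illumination / lens transmittance envelope).

Geometry conventions (shared with :mod:`wedgescan.geometry`):

* Both cameras are rotated 90° versus the stage — image rows run along
  stage X and image columns along stage Y, with pixel index increasing as
  the stage coordinate *decreases*.
* The wedge band index counts from the trailing sensor edge with respect to
  the scan axis (stage X): during a scan stepped by the per-frame distance
  *d*, band ``b+1`` of frame ``f+1`` images the same scene strip as band
  ``b`` of frame ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import Phantom
from .specs import AreaSensorSpec, MagnificationSpec, StagePose, SystemConfig, WedgeSensorSpec

__all__ = [
    "OpticalConfig",
    "NoiseModel",
    "RenderError",
    "VirtualMicroscope",
    "crosstalk_matrix",
]

MAX_BLUR_SIGMA_PX = 25.0

# wavelength samples integrated per RGB channel (nm)
RGB_CHANNEL_SAMPLES = {
    "r": (590.0, 610.0, 630.0),
    "g": (520.0, 545.0, 570.0),
    "b": (460.0, 480.0, 500.0),
}


class RenderError(RuntimeError):
    """Raised when a requested capture cannot be rendered (e.g. the field of
    view falls outside the phantom)."""


def halogen_spectrum(wl_nm: np.ndarray) -> np.ndarray:
    """Halogen-like relative illumination: rises through the blue and is
    practically flat from 500 nm up."""
    wl_nm = np.asarray(wl_nm, dtype=float)
    return 1.0 / (1.0 + np.exp(-(wl_nm - 460.0) / 18.0))


def lens_transmittance(wl_nm: np.ndarray) -> np.ndarray:
    """Objective transmittance: 95% in the visible, declining past 700 nm to
    50% at 1000 nm."""
    wl_nm = np.asarray(wl_nm, dtype=float)
    return 0.95 - 0.45 * np.clip((wl_nm - 700.0) / 300.0, 0.0, 1.0)


@dataclass
class OpticalConfig:
    """Optical-path parameters of the virtual instrument.

    ``light_split`` is the fraction of lamp light sent to the HS path (the
    trinocular sends the remaining 20% to the RGB camera).
    ``defocus_coeff`` is the Gaussian blur radius in μm of scene per μm of
    defocus |z − z*|.  ``crosstalk_strength`` is the fraction of a wedge
    band's response leaked to each spectral neighbor.
    """

    light_split: float = 0.8
    misalignment_deg: float = 0.3
    vignette_strength: float = 0.15
    defocus_coeff: float = 0.1
    crosstalk_strength: float = 0.05
    white_fraction: float = 0.88   # empty-slide level as a fraction of full scale

    def __post_init__(self) -> None:
        if not (0.0 <= self.light_split <= 1.0):
            raise ValueError("light_split must lie in [0, 1]")
        if abs(self.misalignment_deg) > 2.0:
            raise ValueError("misalignment must not exceed 2 degrees in magnitude")
        if not (0.0 <= self.crosstalk_strength < 0.5):
            raise ValueError("crosstalk_strength must lie in [0, 0.5)")

    @classmethod
    def aligned(cls, **kw) -> "OpticalConfig":
        """Convenience: no rotation misalignment (other defaults kept)."""
        kw.setdefault("misalignment_deg", 0.0)
        return cls(**kw)


@dataclass
class NoiseModel:
    """Sensor noise: signal-dependent shot noise plus Gaussian read noise,
    then quantization to the sensor bit depth.  All-zero scales render
    bit-reproducibly; ``quantize=False`` additionally skips rounding, which
    is useful for exact algebraic checks."""

    shot_noise_scale: float = 0.3
    read_noise_dn: float = 1.5
    rng_seed: int = 0
    quantize: bool = True

    @classmethod
    def noiseless(cls, quantize: bool = True) -> "NoiseModel":
        return cls(shot_noise_scale=0.0, read_noise_dn=0.0, quantize=quantize)

    @property
    def is_noiseless(self) -> bool:
        return self.shot_noise_scale == 0.0 and self.read_noise_dn == 0.0


def crosstalk_matrix(n_useful: int, strength: float) -> np.ndarray:
    """Diagonally dominant tridiagonal band-mixing matrix over the useful
    bands in sensor order.  Rows sum to 1; ``strength`` is the per-neighbor
    leak.  Zero strength gives the identity."""
    c = np.eye(n_useful) * (1.0 - 2.0 * strength)
    c[0, 0] = c[-1, -1] = 1.0 - strength
    idx = np.arange(n_useful - 1)
    c[idx, idx + 1] += strength
    c[idx + 1, idx] += strength
    return c


def _vignette(n_rows: int, n_cols: int, strength: float) -> np.ndarray:
    """Radial vignetting factor, 1 at center, (1 − strength) at the corner."""
    r = (np.arange(n_rows) - (n_rows - 1) / 2.0) / max(n_rows / 2.0, 1)
    c = (np.arange(n_cols) - (n_cols - 1) / 2.0) / max(n_cols / 2.0, 1)
    rho2 = (r[:, None] ** 2 + c[None, :] ** 2) / 2.0
    return 1.0 - strength * rho2


class VirtualMicroscope:
    """Deterministic, seeded stand-in for the optical hardware.

    Parameters
    ----------
    phantom
        Ground-truth slide to image.
    system
        Hardware specification (sensors, objectives, stage resolutions).
    optics, noise
        Optical path and sensor noise models; defaults model the physical
        instrument with a 0.3° mount misalignment and mild noise.
    """

    def __init__(self, phantom: Phantom, system: SystemConfig,
                 optics: OpticalConfig | None = None,
                 noise: NoiseModel | None = None) -> None:
        self.phantom = phantom
        self.system = system
        self.optics = optics if optics is not None else OpticalConfig()
        self.noise = noise if noise is not None else NoiseModel()
        ex, ey = phantom.extent_um
        self.pose = StagePose(ex / 2.0, ey / 2.0, 0.0,
                              system.xy_resolution_um, system.z_resolution_um).snapped()
        self.manual_controls_enabled = True
        self._capture_counter = 0

    # -- stage -------------------------------------------------------------

    def move_to(self, x_um: float | None = None, y_um: float | None = None,
                z_um: float | None = None) -> StagePose:
        """Command a stage move; coordinates snap to the axis resolutions."""
        self.pose = self.pose.snapped(x_um, y_um, z_um)
        return self.pose

    def lock_manual_controls(self) -> None:
        self.manual_controls_enabled = False

    def release_manual_controls(self) -> None:
        self.manual_controls_enabled = True

    # -- internals ----------------------------------------------------------

    def _rng(self) -> np.random.Generator:
        rng = np.random.default_rng([self.noise.rng_seed, self._capture_counter])
        self._capture_counter += 1
        return rng

    def _apply_noise(self, signal: np.ndarray, max_value: int,
                     rng: np.random.Generator) -> np.ndarray:
        out = signal
        if not self.noise.is_noiseless:
            shot = self.noise.shot_noise_scale * np.sqrt(np.clip(signal, 0.0, None))
            out = signal + shot * rng.standard_normal(signal.shape)
            out = out + self.noise.read_noise_dn * rng.standard_normal(signal.shape)
        out = np.clip(out, 0.0, max_value)
        if self.noise.quantize:
            out = np.rint(out).astype(np.uint16)
        return out

    def _scene_coords(self, n_rows: int, n_cols: int, pitch_um: float,
                      mag_factor: float, invert_rows: bool = False
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Stage μm coordinates sampled by an n_rows × n_cols pixel grid
        centered on the current pose, including the mount rotation.

        ``invert_rows`` models the HS camera, whose row axis is mounted
        running against stage X: combined with the trailing-edge band
        indexing this makes a scan stepped by *d* satisfy the wedge
        composition rule (cube strip ``s``, band ``b`` ← frame ``s + b``)
        with cube rows mapping linearly and ascending onto the scene.
        """
        p = pitch_um / mag_factor
        r = (np.arange(n_rows) - (n_rows - 1) / 2.0) * p
        if invert_rows:
            r = -r
        c = (np.arange(n_cols) - (n_cols - 1) / 2.0) * p
        rr, cc = np.meshgrid(r, c, indexing="ij")
        th = np.deg2rad(self.optics.misalignment_deg)
        if th != 0.0:
            u = np.cos(th) * rr - np.sin(th) * cc
            v = np.sin(th) * rr + np.cos(th) * cc
        else:
            u, v = rr, cc
        x = self.pose.x_um - u
        y = self.pose.y_um - v
        ex, ey = self.phantom.extent_um
        if x.min() < 0 or x.max() > ex or y.min() < 0 or y.max() > ey:
            raise RenderError(
                f"field of view at pose ({self.pose.x_um:.1f}, {self.pose.y_um:.1f}) "
                f"extends outside the phantom ({ex:.0f} x {ey:.0f} um)"
            )
        return x, y

    def _blur(self, img: np.ndarray, x: np.ndarray, y: np.ndarray,
              pitch_um: float, mag: MagnificationSpec) -> np.ndarray:
        """Defocus blur with spatially varying strength.

        The best-focus stage height is the objective working distance plus
        the phantom's focus relief.  |z − z*(x, y)| is quantized to a few
        levels; the image is blurred at each level and blended per pixel,
        which keeps rendering cheap while letting features at different
        heights (folds) defocus differently.
        """
        relief = ndimage.map_coordinates(
            self.phantom.focus_surface_um,
            np.stack([x / self.phantom.grid_um, y / self.phantom.grid_um]),
            order=1, mode="nearest")
        z_star = mag.working_distance_um + relief
        p = pitch_um / mag.factor
        # blur saturates far from focus (the image is featureless by then)
        sigma = np.minimum(self.optics.defocus_coeff * np.abs(self.pose.z_um - z_star) / p,
                           MAX_BLUR_SIGMA_PX)
        smax = float(sigma.max())
        if smax < 0.05:
            return img
        if float(sigma.min()) > smax - 0.05:  # effectively uniform defocus
            return ndimage.gaussian_filter(img, smax, mode="nearest")
        levels = np.linspace(0.0, smax, 4)
        stack = [img if lv < 0.05 else ndimage.gaussian_filter(img, lv, mode="nearest")
                 for lv in levels]
        idx = np.clip(sigma / levels[1], 0, len(levels) - 1 - 1e-9)
        lo = idx.astype(int)
        frac = idx - lo
        out = np.empty_like(img)
        stacked = np.stack(stack)
        take = np.take_along_axis(stacked, lo[None], axis=0)[0]
        take_hi = np.take_along_axis(stacked, (lo + 1)[None], axis=0)[0]
        out = take * (1 - frac) + take_hi * frac
        return out

    # -- RGB path -----------------------------------------------------------

    def _rgb_white_level(self) -> float:
        return self.optics.white_fraction * self.system.rgb.max_value

    def capture_rgb(self, mag_factor: float,
                    sensor: AreaSensorSpec | None = None) -> np.ndarray:
        """Render an RGB capture (rows × cols × 3, quantized to the sensor
        bit depth) at the current pose."""
        rgb = sensor if sensor is not None else self.system.rgb
        mag = self.system.magnification(mag_factor)
        x, y = self._scene_coords(rgb.height_px, rgb.width_px, rgb.pixel_pitch_um, mag.factor)
        labels, texture = self.phantom.sample_fields(x, y)
        vign = _vignette(rgb.height_px, rgb.width_px, self.optics.vignette_strength)
        rng = self._rng()
        channels = []
        for name in ("r", "g", "b"):
            wl = np.asarray(RGB_CHANNEL_SAMPLES[name])
            weights = halogen_spectrum(wl) * lens_transmittance(wl)
            base = self.phantom.class_base_transmittance(wl)  # (n_classes, 3)
            t = (base[labels] ** texture[..., None] * weights).sum(-1) / weights.sum()
            t = np.where(labels == 0, 1.0, t)
            img = self._rgb_white_level() * t
            img = self._blur(img, x, y, rgb.pixel_pitch_um, mag)
            channels.append(img * vign)
        signal = np.stack(channels, axis=-1)
        return self._apply_noise(signal, rgb.max_value, rng)

    def capture_rgb_white(self, mag_factor: float,
                          sensor: AreaSensorSpec | None = None) -> np.ndarray:
        """Empty-slide RGB capture at the same exposure (flat-field
        reference); carries the vignetting but no scene content."""
        rgb = sensor if sensor is not None else self.system.rgb
        self.system.magnification(mag_factor)
        vign = _vignette(rgb.height_px, rgb.width_px, self.optics.vignette_strength)
        rng = self._rng()
        signal = np.repeat((self._rgb_white_level() * vign)[..., None], 3, axis=-1)
        return self._apply_noise(signal, rgb.max_value, rng)

    # -- HS path ------------------------------------------------------------

    def _hs_band_weights(self, spec: WedgeSensorSpec) -> tuple[np.ndarray, np.ndarray, float]:
        """(crosstalk matrix C, per-band illumination weights w, gain) over
        the useful bands in sensor order.  The gain scales the brightest
        white-reference band to ``white_fraction`` of full scale."""
        useful = spec.useful_indices
        wl = spec.band_wavelengths_nm[useful]
        w = halogen_spectrum(wl) * lens_transmittance(wl) * self.optics.light_split
        c = crosstalk_matrix(useful.size, self.optics.crosstalk_strength)
        white = c @ w
        gain = self.optics.white_fraction * spec.max_value / white.max()
        return c, w, gain

    def _hs_signal(self, spec: WedgeSensorSpec, mag: MagnificationSpec,
                   white_only: bool) -> np.ndarray:
        """Noise-free HS frame signal (float), full sensor size."""
        n_th, bh = spec.n_theoretical_bands, spec.band_height_px
        fp_rows = n_th * bh
        c, w, gain = self._hs_band_weights(spec)
        cw = c * w[None, :]           # row t: per-source-band weights
        white_level = cw.sum(axis=1)  # (n_useful,)
        vign = _vignette(fp_rows, spec.width_px, self.optics.vignette_strength)
        frame = np.zeros((spec.height_px, spec.width_px))
        useful = spec.useful_indices
        if white_only:
            for u, t in enumerate(useful):
                rows = spec.band_rows(int(t))
                frame[rows] = gain * white_level[u] * vign[rows]
            return frame

        x, y = self._scene_coords(fp_rows, spec.width_px, spec.pixel_pitch_um,
                                  mag.factor, invert_rows=True)
        labels, texture = self.phantom.sample_fields(x, y)
        wl_useful = spec.band_wavelengths_nm[useful]
        base = self.phantom.class_base_transmittance(wl_useful)  # (n_classes, n_useful)
        # transmittance of every footprint pixel at every useful wavelength,
        # band-mixed by the crosstalk matrix at the same spatial location
        for u, t in enumerate(useful):
            rows = spec.band_rows(int(t))
            sources = np.flatnonzero(cw[u])
            tvals = base[labels[rows]][..., sources] ** texture[rows][..., None]
            tvals = np.where(labels[rows][..., None] == 0, 1.0, tvals)
            mixed = (tvals * cw[u, sources]).sum(-1)
            frame[rows] = gain * mixed * vign[rows]
        z_star = mag.working_distance_um + self.phantom.focus_at(self.pose.x_um, self.pose.y_um)
        sigma = min(self.optics.defocus_coeff * abs(self.pose.z_um - z_star)
                    / (spec.pixel_pitch_um / mag.factor), MAX_BLUR_SIGMA_PX)
        if sigma >= 0.05:
            frame[: fp_rows] = ndimage.gaussian_filter(frame[: fp_rows], sigma, mode="nearest")
        return frame

    def capture_hs_frame(self, mag_factor: float,
                         spec: WedgeSensorSpec | None = None) -> np.ndarray:
        """Render one wedge frame (height × width, 10-bit in uint16) at the
        current pose.  Dead bands and residual sensor rows read baseline."""
        spec = spec if spec is not None else self.system.wedge
        mag = self.system.magnification(mag_factor)
        rng = self._rng()
        signal = self._hs_signal(spec, mag, white_only=False)
        return self._apply_noise(signal, spec.max_value, rng)

    def capture_white_frame(self, mag_factor: float,
                            spec: WedgeSensorSpec | None = None) -> np.ndarray:
        """White reference: a capture of an empty (non-sample) area at the
        same exposure."""
        spec = spec if spec is not None else self.system.wedge
        mag = self.system.magnification(mag_factor)
        rng = self._rng()
        signal = self._hs_signal(spec, mag, white_only=True)
        return self._apply_noise(signal, spec.max_value, rng)

    def capture_dark_frame(self, spec: WedgeSensorSpec | None = None) -> np.ndarray:
        """Dark reference: optical path covered, baseline read noise only."""
        spec = spec if spec is not None else self.system.wedge
        rng = self._rng()
        signal = np.zeros((spec.height_px, spec.width_px))
        return self._apply_noise(signal, spec.max_value, rng)


def correction_matrix(spec: WedgeSensorSpec, optics: OpticalConfig
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Manufacturer-style spectral-correction matrix for the virtual wedge
    camera, derived from the known crosstalk and illumination envelope.

    A calibrated (white-normalized) pixel spectrum t over the useful bands
    in sensor order satisfies ``t = D⁻¹ C W T`` where ``C`` is the crosstalk
    matrix, ``W = diag(w)`` the per-band illumination weights and
    ``D = diag(C w)`` the white normalization.  The exact inverse map,
    reordered to ascending wavelength by the permutation ``P``, is

        M = P · W⁻¹ · C⁻¹ · D

    Returns ``(M, wavelengths_ascending)``.
    """
    useful = spec.useful_indices
    wl = spec.band_wavelengths_nm[useful]
    w = halogen_spectrum(wl) * lens_transmittance(wl) * optics.light_split
    c = crosstalk_matrix(useful.size, optics.crosstalk_strength)
    m = np.diag(1.0 / w) @ np.linalg.inv(c) @ np.diag(c @ w)
    order = np.argsort(wl, kind="stable")
    return m[order], wl[order]


def reference_calibration(microscope: VirtualMicroscope, mag_factor: float,
                          spec: WedgeSensorSpec | None = None):
    """Capture white/dark reference frames on the virtual instrument and
    pair them with the exact spectral-correction matrix (the stand-in for
    the matrix a camera manufacturer would ship)."""
    from .hs_preprocess import CalibrationSet

    spec = spec if spec is not None else microscope.system.wedge
    white = microscope.capture_white_frame(mag_factor, spec)
    dark = microscope.capture_dark_frame(spec)
    m, wl = correction_matrix(spec, microscope.optics)
    return CalibrationSet(
        white_frame=white, dark_frame=dark,
        spectral_correction=m, corrected_wavelengths_nm=wl,
    )
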