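"""Synthetic tissue phantom: the ground truth behind the virtual microscope.

A :class:`Phantom` is a flat "slide" carrying a per-pixel tissue class map
(elliptical nucleus-like blobs, ridge-like vessels, empty background), a
multiplicative optical-density texture, per-class smooth absorbance spectra,
and a smooth best-focus height surface z*(x, y) emulating the micrometric
relief of real sections.  Transmittance follows Beer–Lambert:
``T(x, y, λ) = 10^(−A_class(λ) · texture(x, y))`` with the background exactly
transparent.

Everything is deterministic per seed, so acquisition and processing
algorithms can be validated by parameter recovery against this ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["Phantom", "make_phantom", "load_phantom", "densest_tissue_position"]

# Fine wavelength grid on which class absorbance spectra are tabulated (nm).
WL_MIN, WL_MAX, WL_STEP = 450.0, 950.0, 2.0


@dataclass
class Phantom:
    """Ground-truth slide.

    Field arrays are indexed ``[i, j]`` with ``i`` along stage X and ``j``
    along stage Y; node ``(i, j)`` sits at stage position
    ``(i · grid_um, j · grid_um)``.
    """

    label_map: np.ndarray          # (nx, ny) int8 tissue class, 0 = background
    texture_field: np.ndarray      # (nx, ny) multiplicative density in (0, 1]
    focus_surface_um: np.ndarray   # (nx, ny) best-focus height z*(x, y), relative
    #                                to the objective's nominal working distance
    #                                (0 = perfectly parfocal sample)
    absorbance_wl_nm: np.ndarray   # (n_wl,) fine wavelength grid
    class_absorbance: np.ndarray   # (n_classes, n_wl), row 0 all zeros
    grid_um: float
    seed: int

    @property
    def n_classes(self) -> int:
        return self.class_absorbance.shape[0]

    @property
    def extent_um(self) -> tuple[float, float]:
        return ((self.label_map.shape[0] - 1) * self.grid_um,
                (self.label_map.shape[1] - 1) * self.grid_um)

    # -- continuous-coordinate sampling -------------------------------------

    def _check_bounds(self, x_um: np.ndarray, y_um: np.ndarray) -> None:
        ex, ey = self.extent_um
        eps = 1e-6
        if (np.min(x_um) < -eps or np.max(x_um) > ex + eps
                or np.min(y_um) < -eps or np.max(y_um) > ey + eps):
            raise ValueError(
                f"requested position outside phantom extent {ex:.1f} x {ey:.1f} um"
            )

    def sample_fields(self, x_um: np.ndarray, y_um: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Tissue class (nearest node) and texture (bilinear) at stage
        positions; arrays broadcast elementwise."""
        x_um = np.asarray(x_um, dtype=float)
        y_um = np.asarray(y_um, dtype=float)
        self._check_bounds(x_um, y_um)
        shape = np.broadcast_shapes(x_um.shape, y_um.shape)
        coords = np.stack([np.broadcast_to(x_um, shape).ravel() / self.grid_um,
                           np.broadcast_to(y_um, shape).ravel() / self.grid_um])
        labels = ndimage.map_coordinates(self.label_map, coords, order=0,
                                         mode="nearest").reshape(shape)
        texture = ndimage.map_coordinates(self.texture_field, coords, order=1,
                                          mode="nearest").reshape(shape)
        return labels, texture

    def class_base_transmittance(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """10^(−A_c(λ)) per class at the given wavelengths, shape
        (n_classes, n_wl); class 0 is exactly 1."""
        wavelengths_nm = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        absorb = np.empty((self.n_classes, wavelengths_nm.size))
        for c in range(self.n_classes):
            absorb[c] = np.interp(wavelengths_nm, self.absorbance_wl_nm, self.class_absorbance[c])
        base = 10.0 ** (-absorb)
        base[0] = 1.0
        return base

    def transmittance_at(self, x_um, y_um, wavelength_nm) -> np.ndarray | float:
        """Transmittance fraction in [0, 1] at a stage position and
        wavelength.  Background returns exactly 1.0."""
        labels, texture = self.sample_fields(x_um, y_um)
        base = self.class_base_transmittance(np.atleast_1d(wavelength_nm))
        t = base[labels] ** np.asarray(texture)[..., None]
        t = np.where(labels[..., None] == 0, 1.0, t)
        if np.isscalar(wavelength_nm) or np.ndim(wavelength_nm) == 0:
            t = t[..., 0]
        if t.ndim == 0:
            return float(t)
        return t

    def focus_at(self, x_um, y_um) -> np.ndarray | float:
        """Best-focus height z*(x, y) in μm (bilinear)."""
        x_um = np.asarray(x_um, dtype=float)
        y_um = np.asarray(y_um, dtype=float)
        self._check_bounds(x_um, y_um)
        shape = np.broadcast_shapes(x_um.shape, y_um.shape)
        coords = np.stack([np.broadcast_to(x_um, shape).ravel() / self.grid_um,
                           np.broadcast_to(y_um, shape).ravel() / self.grid_um])
        z = ndimage.map_coordinates(self.focus_surface_um, coords, order=1,
                                    mode="nearest").reshape(shape)
        return float(z) if z.ndim == 0 else z

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the field arrays to ``<path>`` (NumPy container) plus a JSON
        ground-truth sidecar ``<path>.json`` for use by tests and tools."""
        path = Path(path)
        np.savez_compressed(
            path,
            label_map=self.label_map,
            texture_field=self.texture_field,
            focus_surface_um=self.focus_surface_um,
            absorbance_wl_nm=self.absorbance_wl_nm,
            class_absorbance=self.class_absorbance,
            grid_um=self.grid_um,
            seed=self.seed,
        )
        sidecar = {
            "seed": int(self.seed),
            "grid_um": float(self.grid_um),
            "extent_um": list(self.extent_um),
            "n_classes": int(self.n_classes),
            "focus_mean_um": float(self.focus_surface_um.mean()),
            "focus_min_um": float(self.focus_surface_um.min()),
            "focus_max_um": float(self.focus_surface_um.max()),
            "class_absorbance_peak": [float(a.max()) for a in self.class_absorbance],
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(path: str | Path) -> Phantom:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with np.load(path) as z:
        return Phantom(
            label_map=z["label_map"],
            texture_field=z["texture_field"],
            focus_surface_um=z["focus_surface_um"],
            absorbance_wl_nm=z["absorbance_wl_nm"],
            class_absorbance=z["class_absorbance"],
            grid_um=float(z["grid_um"]),
            seed=int(z["seed"]),
        )


def densest_tissue_position(phantom: Phantom, fov_um: tuple[float, float],
                            margin_um: float = 0.0) -> tuple[float, float]:
    """Stage position whose ``fov_um`` (stage X × Y) window covers the most
    tissue — where an operator would point the instrument.

    The window (plus ``margin_um`` on all sides) is kept inside the phantom.
    """
    wx = max(1, int(round(fov_um[0] / phantom.grid_um)))
    wy = max(1, int(round(fov_um[1] / phantom.grid_um)))
    cover = ndimage.uniform_filter((phantom.label_map > 0).astype(float),
                                   size=(wx, wy), mode="constant")
    mx = int(np.ceil((fov_um[0] / 2.0 + margin_um) / phantom.grid_um)) + 1
    my = int(np.ceil((fov_um[1] / 2.0 + margin_um) / phantom.grid_um)) + 1
    interior = np.full(cover.shape, -1.0)
    interior[mx:-mx or None, my:-my or None] = cover[mx:-mx or None, my:-my or None]
    i, j = np.unravel_index(np.argmax(interior), interior.shape)
    return float(i * phantom.grid_um), float(j * phantom.grid_um)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Zero-mean smooth random field normalized to peak magnitude 1."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _distinct_spectra(rng: np.random.Generator, n_classes: int,
                      wl: np.ndarray, min_l2: float = 2.0) -> np.ndarray:
    """Smooth Gaussian-mixture absorbance curves, mutually separated by at
    least ``min_l2`` in L2 distance (resampled deterministically until so)."""
    spectra = [np.zeros_like(wl)]  # background
    for _ in range(n_classes - 1):
        for _attempt in range(200):
            a = np.zeros_like(wl)
            for _k in range(3):
                amp = rng.uniform(0.25, 0.9)
                mu = rng.uniform(480.0, 890.0)
                sig = rng.uniform(40.0, 120.0)
                a += amp * np.exp(-0.5 * ((wl - mu) / sig) ** 2)
            if all(np.linalg.norm(a - s) >= min_l2 for s in spectra):
                spectra.append(a)
                break
        else:  # pragma: no cover - generator parameters make this unreachable
            raise RuntimeError("could not draw mutually distinct class spectra")
    return np.stack(spectra)


def make_phantom(seed: int,
                 extent_um: tuple[float, float] = (2000.0, 2000.0),
                 n_classes: int = 4,
                 grid_um: float = 1.0,
                 focus_base_um: float = 0.0,
                 focus_amplitude_um: float = 8.0,
                 blob_density: float = 1.2e-4,
                 background_fraction_target: float = 0.35) -> Phantom:
    """Generate a deterministic textured tissue phantom.

    Parameters
    ----------
    seed
        Fixes every random choice; identical seeds give identical phantoms.
    extent_um
        Physical slide size (stage X, stage Y) in μm.
    n_classes
        Total classes including background (≥ 2).  Class 1 receives
        elliptical nucleus-like blobs; class 2 (when present) additionally
        ridge-like vessels; further classes more blobs.
    grid_um
        Ground-truth sampling pitch.  1 μm resolves the finest camera pixel
        the default objectives produce.
    focus_base_um, focus_amplitude_um
        Mean and peak deviation of the smooth best-focus relief z*(x, y),
        expressed relative to the objective's nominal working distance
        (the sample is parfocal on average when the base is 0).
    blob_density
        Expected blobs per μm²; with the default the slide is roughly
        two-thirds covered by tissue.
    """
    if n_classes < 2:
        raise ValueError("need at least background + one tissue class")
    if extent_um[0] <= 0 or extent_um[1] <= 0:
        raise ValueError("phantom extent must be positive")
    rng = np.random.default_rng(seed)
    nx = int(round(extent_um[0] / grid_um)) + 1
    ny = int(round(extent_um[1] / grid_um)) + 1

    label = np.zeros((nx, ny), dtype=np.int8)
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    area = extent_um[0] * extent_um[1]
    n_blobs = max(3, int(blob_density * area))
    tissue_classes = list(range(1, n_classes))
    for b in range(n_blobs):
        c = tissue_classes[b % len(tissue_classes)]
        cx = rng.uniform(0, nx - 1)
        cy = rng.uniform(0, ny - 1)
        a_ax = rng.uniform(12, 60) / grid_um * 0.5
        b_ax = a_ax * rng.uniform(0.4, 1.0)
        th = rng.uniform(0, np.pi)
        u = (ii - cx) * np.cos(th) + (jj - cy) * np.sin(th)
        v = -(ii - cx) * np.sin(th) + (jj - cy) * np.cos(th)
        label[(u / a_ax) ** 2 + (v / b_ax) ** 2 <= 1.0] = c

    if n_classes >= 3:
        # ridge-like "vessels": sinuous curves of class 2
        n_vessels = max(1, int(area / 6e5))
        for _ in range(n_vessels):
            j0 = rng.uniform(0.1, 0.9) * (ny - 1)
            amp = rng.uniform(0.02, 0.1) * (ny - 1)
            freq = rng.uniform(1.0, 3.0) * 2 * np.pi / max(nx, 2)
            phase = rng.uniform(0, 2 * np.pi)
            width = rng.uniform(4, 10) / grid_um * 0.5 + 1.0
            center = j0 + amp * np.sin(freq * ii[:, 0] + phase)
            dist = np.abs(jj - center[:, None])
            label[dist <= width] = 2

    # multiplicative density texture: smooth variation plus two speckle
    # scales, the finest ~1 um, so tissue interiors carry the high spatial
    # frequency that focus scoring and keypoint detection rely on
    coarse = _smooth_field(rng, (nx, ny), sigma=max(2.0, 12.0 / grid_um))
    fine = _smooth_field(rng, (nx, ny), sigma=max(0.8, 1.6 / grid_um))
    speckle = _smooth_field(rng, (nx, ny), sigma=max(0.5, 0.5 / grid_um))
    texture = np.clip(0.62 + 0.14 * coarse + 0.16 * fine + 0.22 * speckle, 0.05, 1.0)

    focus = focus_base_um + focus_amplitude_um * _smooth_field(
        rng, (nx, ny), sigma=max(8.0, 120.0 / grid_um))

    wl = np.arange(WL_MIN, WL_MAX + WL_STEP / 2, WL_STEP)
    spectra = _distinct_spectra(rng, n_classes, wl)

    return Phantom(
        label_map=label,
        texture_field=texture.astype(np.float32),
        focus_surface_um=focus.astype(np.float64),
        absorbance_wl_nm=wl,
        class_absorbance=spectra,
        grid_um=float(grid_um),
        seed=int(seed),
    )
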