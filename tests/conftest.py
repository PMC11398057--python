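"""Shared fixtures: reduced instrument configs and seeded phantoms.

Simulation-driven tests run on scaled-down sensors that preserve every
geometric relation of the full instrument (wedge band layout, 90° camera
rotation, half-overlap grids) while rendering in milliseconds; geometry
tests use the full-size specification directly.
"""

from __future__ import annotations

import numpy as np
import pytest

from wedgescan import (
    NoiseModel,
    OpticalConfig,
    SystemConfig,
    VirtualMicroscope,
    default_system,
    make_phantom,
)
from wedgescan.demo import demo_system


@pytest.fixture(scope="session")
def full_system() -> SystemConfig:
    """The physical instrument's specification (Table-1 scale)."""
    return default_system()


@pytest.fixture(scope="session")
def small_system() -> SystemConfig:
    """Reduced instrument: 8-band wedge (6 useful), 96×72 RGB sensor."""
    return demo_system()


@pytest.fixture(scope="session")
def tissue_phantom():
    """A deterministic 3-class phantom with flat focus (z* = working
    distance everywhere), shared across read-only tests."""
    return make_phantom(11, extent_um=(240.0, 240.0), n_classes=3,
                        grid_um=0.5, focus_amplitude_um=0.0)


@pytest.fixture()
def make_microscope(small_system):
    """Factory for microscopes over a given phantom with chosen optics."""

    def factory(phantom=None, optics=None, noise=None, seed=0):
        ph = phantom if phantom is not None else make_phantom(
            seed, extent_um=(240.0, 240.0), n_classes=3,
            grid_um=0.5, focus_amplitude_um=0.0)
        return VirtualMicroscope(
            ph, small_system,
            optics=optics if optics is not None else OpticalConfig.aligned(),
            noise=noise if noise is not None else NoiseModel.noiseless(),
        )

    return factory


@pytest.fixture()
def noiseless_exact() -> NoiseModel:
    """Zero noise and no quantization: for exact algebraic checks."""
    return NoiseModel.noiseless(quantize=False)


def flat_spectrum_phantom(seed: int = 5, extent: float = 240.0):
    """Phantom whose class spectra are wavelength-flat, so transmittance
    depends on position only (used to test scan geometry claims)."""
    ph = make_phantom(seed, extent_um=(extent, extent), n_classes=3,
                      grid_um=0.5, focus_amplitude_um=0.0)
    for c in range(1, ph.n_classes):
        ph.class_absorbance[c] = ph.class_absorbance[c].mean()
    return ph
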