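"""Hardware specification records for the microscope components.

These dataclasses carry the static geometry of the two cameras, the
objective lenses and the motorized stage.  They are pure parameter
containers: all scan mathematics built on top of them lives in
:mod:`wedgescan.geometry`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "WedgeSensorSpec",
    "AreaSensorSpec",
    "MagnificationSpec",
    "StagePose",
    "SystemConfig",
    "default_wedge_sensor",
    "default_rgb_sensor",
    "default_magnifications",
    "default_system",
]


def _descending_wavelengths(n_bands: int, lo: float = 470.0, hi: float = 900.0) -> np.ndarray:
    """Wavelength of each wedge band in sensor order (descending, nm).

    The wedge filter lays the longest wavelength at band index 0; the
    spectral-correction step owns the reordering to ascending order.
    """
    if n_bands == 1:
        return np.array([(lo + hi) / 2.0])
    return hi - np.arange(n_bands) * (hi - lo) / (n_bands - 1)


def _edge_dead_mask(n_theoretical: int, n_dead: int) -> np.ndarray:
    """Default useful-band mask: dead bands split between both sensor edges.

    Which physical band indices are dead is manufacturer-specific, so the mask
    is configurable; the default keeps a contiguous block of useful bands.
    """
    mask = np.ones(n_theoretical, dtype=bool)
    lead = n_dead // 2
    trail = n_dead - lead
    if lead:
        mask[:lead] = False
    if trail:
        mask[n_theoretical - trail:] = False
    return mask


@dataclass
class WedgeSensorSpec:
    """Geometry of the wedge-linescan hyperspectral sensor.

    The filter stripes ("bands") each cover ``band_height_px`` sensor rows.
    Band index ``b`` occupies the row block counted from the *trailing* edge
    of the sensor with respect to the scan direction (see ``band_rows``), so
    that during a scan band ``b`` of frame ``f`` images scene strip
    ``f + n_theoretical_bands - 1 - b``.
    """

    width_px: int = 2048
    height_px: int = 1088
    band_height_px: int = 5
    n_theoretical_bands: int = 216
    n_useful_bands: int = 145
    pixel_pitch_um: float = 5.5
    bit_depth: int = 10
    useful_band_mask: np.ndarray | None = None
    band_wavelengths_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.useful_band_mask is None:
            self.useful_band_mask = _edge_dead_mask(
                self.n_theoretical_bands, self.n_theoretical_bands - self.n_useful_bands
            )
        self.useful_band_mask = np.asarray(self.useful_band_mask, dtype=bool)
        if self.band_wavelengths_nm is None:
            self.band_wavelengths_nm = _descending_wavelengths(self.n_theoretical_bands)
        self.band_wavelengths_nm = np.asarray(self.band_wavelengths_nm, dtype=float)
        self.validate()

    @property
    def n_dead_bands(self) -> int:
        return self.n_theoretical_bands - self.n_useful_bands

    @property
    def useful_indices(self) -> np.ndarray:
        """Theoretical band indices that carry signal, in sensor band order."""
        return np.flatnonzero(self.useful_band_mask)

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    def band_rows(self, b: int) -> slice:
        """Sensor row block of band ``b`` (trailing-edge indexing)."""
        k = self.n_theoretical_bands - 1 - b
        h = self.band_height_px
        return slice(k * h, (k + 1) * h)

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.band_height_px <= 0:
            raise ValueError("sensor dimensions must be positive")
        if self.n_theoretical_bands * self.band_height_px > self.height_px + self.band_height_px:
            raise ValueError("bands do not tile the sensor")
        if self.useful_band_mask.size != self.n_theoretical_bands:
            raise ValueError("useful_band_mask length must equal n_theoretical_bands")
        if int(self.useful_band_mask.sum()) != self.n_useful_bands:
            raise ValueError("useful_band_mask population must equal n_useful_bands")
        wl = self.band_wavelengths_nm
        if wl.size != self.n_theoretical_bands:
            raise ValueError("one wavelength per theoretical band required")
        if wl.min() < 470.0 - 1e-9 or wl.max() > 900.0 + 1e-9:
            raise ValueError("band wavelengths must lie within [470, 900] nm")


@dataclass
class AreaSensorSpec:
    """Geometry of the area-scan RGB camera sensor."""

    width_px: int = 5472
    height_px: int = 3648
    pixel_pitch_um: float = 2.4
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) <= 0:
            raise ValueError("sensor dimensions must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.bit_depth <= 0:
            raise ValueError("bit depth must be positive")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class MagnificationSpec:
    """One objective lens: magnification factor, working distance and the
    default Z displacement used by the autofocus routine (all in μm where
    applicable)."""

    factor: float
    working_distance_um: float
    af_default_step_um: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("magnification factor must be positive")
        if self.working_distance_um <= 0:
            raise ValueError("working distance must be positive")
        if self.af_default_step_um <= 0:
            raise ValueError("autofocus step must be positive")


@dataclass
class StagePose:
    """Commanded stage position; moves snap to the axis resolution."""

    x_um: float = 0.0
    y_um: float = 0.0
    z_um: float = 0.0
    xy_resolution_um: float = 0.02
    z_resolution_um: float = 0.1

    def __post_init__(self) -> None:
        if self.xy_resolution_um <= 0 or self.z_resolution_um <= 0:
            raise ValueError("stage resolutions must be positive")

    def snapped(self, x_um: float | None = None, y_um: float | None = None,
                z_um: float | None = None) -> "StagePose":
        """Return a new pose with the given coordinates snapped to the
        nearest integer multiple of the corresponding axis resolution."""
        def snap(v: float, res: float) -> float:
            return round(v / res) * res

        return StagePose(
            x_um=snap(self.x_um if x_um is None else x_um, self.xy_resolution_um),
            y_um=snap(self.y_um if y_um is None else y_um, self.xy_resolution_um),
            z_um=snap(self.z_um if z_um is None else z_um, self.z_resolution_um),
            xy_resolution_um=self.xy_resolution_um,
            z_resolution_um=self.z_resolution_um,
        )


def default_wedge_sensor() -> WedgeSensorSpec:
    """The 2048×1088, 216-band (145 useful) wedge sensor."""
    return WedgeSensorSpec()


def default_rgb_sensor() -> AreaSensorSpec:
    """The 5472×3648 RGB area sensor, 2.4 μm pitch."""
    return AreaSensorSpec()


def default_magnifications() -> dict[float, MagnificationSpec]:
    """The three objectives: 4×, 10× and 40× with their working distances
    (470/350/340 μm) and autofocus default steps (10/5/1 μm)."""
    return {
        4.0: MagnificationSpec(4.0, 470.0, 10.0),
        10.0: MagnificationSpec(10.0, 350.0, 5.0),
        40.0: MagnificationSpec(40.0, 340.0, 1.0),
    }


@dataclass
class SystemConfig:
    """Complete adaptation surface of the instrument: both sensors, the lens
    set and the stage resolutions.  Serializable to a human-readable JSON
    config file (see ``save``/``load``)."""

    wedge: WedgeSensorSpec = field(default_factory=default_wedge_sensor)
    rgb: AreaSensorSpec = field(default_factory=default_rgb_sensor)
    magnifications: dict[float, MagnificationSpec] = field(default_factory=default_magnifications)
    xy_resolution_um: float = 0.02
    z_resolution_um: float = 0.1

    def magnification(self, factor: float) -> MagnificationSpec:
        try:
            return self.magnifications[float(factor)]
        except KeyError:
            raise KeyError(f"no objective with magnification {factor}x configured") from None

    def home_pose(self, mag_factor: float | None = None,
                  x_um: float = 0.0, y_um: float = 0.0) -> StagePose:
        z = 0.0
        if mag_factor is not None:
            z = self.magnification(mag_factor).working_distance_um
        return StagePose(x_um, y_um, z, self.xy_resolution_um, self.z_resolution_um).snapped()

    def to_dict(self) -> dict:
        d = {
            "wedge": asdict(self.wedge),
            "rgb": asdict(self.rgb),
            "magnifications": {str(k): asdict(v) for k, v in self.magnifications.items()},
            "xy_resolution_um": self.xy_resolution_um,
            "z_resolution_um": self.z_resolution_um,
        }
        d["wedge"]["useful_band_mask"] = self.wedge.useful_band_mask.astype(int).tolist()
        d["wedge"]["band_wavelengths_nm"] = self.wedge.band_wavelengths_nm.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SystemConfig":
        wedge = d["wedge"].copy()
        wedge["useful_band_mask"] = np.asarray(wedge["useful_band_mask"], dtype=bool)
        wedge["band_wavelengths_nm"] = np.asarray(wedge["band_wavelengths_nm"], dtype=float)
        return cls(
            wedge=WedgeSensorSpec(**wedge),
            rgb=AreaSensorSpec(**d["rgb"]),
            magnifications={
                float(k): MagnificationSpec(**v) for k, v in d["magnifications"].items()
            },
            xy_resolution_um=d.get("xy_resolution_um", 0.02),
            z_resolution_um=d.get("z_resolution_um", 0.1),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SystemConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_system() -> SystemConfig:
    return SystemConfig()
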