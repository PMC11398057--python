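"""Hyperspectral scan driver.

Plans the stage trajectory of a wedge-linescan scan (``n_frames`` poses a
step *d* apart, starting half the scan length before the region center),
executes it against a microscope, and persists the resulting frame stack
through a pluggable bit-exact lossless codec.  The default codec stores the
10-bit frames in a multi-page grayscale TIFF with zlib/deflate compression
(16-bit little-endian containers).

Folder layout mirrors the instrument software: ``<sample_id>/data/<mag>/``
holding the raw container and a JSON scan-information record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import tifffile

from . import geometry
from .specs import MagnificationSpec, StagePose, WedgeSensorSpec

__all__ = [
    "RawHSScan",
    "ScanInfoRecord",
    "LosslessCodec",
    "TiffDeflateCodec",
    "plan_hs_scan",
    "run_hs_scan",
    "save_raw",
    "load_raw",
]

log = logging.getLogger(__name__)


@dataclass
class ScanInfoRecord:
    """JSON-serializable record of one HS scan."""

    sample_id: str
    magnification: float
    n_frames: int
    step_um: float
    start_xy_um: tuple[float, float]
    end_xy_um: tuple[float, float]
    z_um: float
    is_white_reference: bool = False
    exposure_tag: str = "default"
    timestamp: str = ""
    folder_path: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScanInfoRecord":
        d = json.loads(text)
        d["start_xy_um"] = tuple(d["start_xy_um"])
        d["end_xy_um"] = tuple(d["end_xy_um"])
        return cls(**d)


@dataclass
class RawHSScan:
    """An ordered stack of wedge frames plus scan metadata — the unit the
    preprocessing chain consumes."""

    frames: np.ndarray            # (n_frames, height_px, width_px) uint16, 10-bit
    info: ScanInfoRecord
    bit_depth: int = 10

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) stack")
        if self.frames.shape[0] != self.info.n_frames:
            raise ValueError("frame count does not match scan info")
        if self.frames.size and int(self.frames.max()) > (1 << self.bit_depth) - 1:
            raise ValueError(f"frame values exceed {self.bit_depth}-bit range")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def plan_hs_scan(spec: WedgeSensorSpec, mag: MagnificationSpec, n_frames: int,
                 center_pose: StagePose) -> list[StagePose]:
    """Stage poses of an HS scan centered on ``center_pose``.

    The first pose is offset from the center by half the scan length along
    the scan axis (stage X); consecutive poses differ by the per-frame step
    *d*, snapped to the stage resolution.
    """
    n_min = geometry.min_scan_frames(spec)
    if n_frames < n_min:
        raise ValueError(f"n_frames={n_frames} below the minimum {n_min}")
    d = geometry.step_distance(spec, mag)
    length = geometry.scan_length_um(spec, n_frames, mag)
    start_x = center_pose.x_um - length / 2.0
    return [center_pose.snapped(x_um=start_x + f * d) for f in range(n_frames)]


def run_hs_scan(microscope, plan: list[StagePose], *, sample_id: str,
                mag: MagnificationSpec, spec: WedgeSensorSpec | None = None,
                is_white_reference: bool = False,
                work_dir: str | Path | None = None,
                record_timestamp: bool = False) -> RawHSScan:
    """Execute a planned scan: capture one frame per pose, in order.

    Manual controls are locked during the scan; the stage returns to the
    pre-scan pose afterwards.  If ``work_dir`` is given the instrument
    folder layout ``<sample_id>/data/<mag>/`` is created before capture.
    When a white reference is requested the empty-slide optical path is
    rendered instead of the sample.
    """
    if not plan:
        raise ValueError("empty scan plan")
    spec = spec if spec is not None else microscope.system.wedge
    folder = ""
    if work_dir is not None:
        folder_path = Path(work_dir) / sample_id / "data" / f"{mag.factor:g}x"
        folder_path.mkdir(parents=True, exist_ok=True)
        folder = str(folder_path)

    pre_pose = microscope.pose
    microscope.lock_manual_controls()
    captured: list[np.ndarray] = []
    try:
        for pose in plan:
            microscope.move_to(x_um=pose.x_um, y_um=pose.y_um)
            if is_white_reference:
                captured.append(microscope.capture_white_frame(mag.factor, spec))
            else:
                captured.append(microscope.capture_hs_frame(mag.factor, spec))
    except Exception:
        # partial scan discarded, stage restored
        microscope.move_to(x_um=pre_pose.x_um, y_um=pre_pose.y_um, z_um=pre_pose.z_um)
        microscope.release_manual_controls()
        raise
    microscope.move_to(x_um=pre_pose.x_um, y_um=pre_pose.y_um, z_um=pre_pose.z_um)
    microscope.release_manual_controls()
    frames = np.stack(captured)

    info = ScanInfoRecord(
        sample_id=sample_id,
        magnification=mag.factor,
        n_frames=len(plan),
        step_um=geometry.step_distance(spec, mag),
        start_xy_um=(plan[0].x_um, plan[0].y_um),
        end_xy_um=(plan[-1].x_um, plan[-1].y_um),
        z_um=microscope.pose.z_um,
        is_white_reference=is_white_reference,
        timestamp=datetime.now(timezone.utc).isoformat() if record_timestamp else "",
        folder_path=folder,
    )
    return RawHSScan(frames=frames, info=info, bit_depth=spec.bit_depth)


class LosslessCodec:
    """Contract for raw-scan containers: any multi-frame grayscale format
    whose round trip is bit-exact qualifies."""

    extension = ".raw"

    def write(self, path: Path, frames: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError

    def read(self, path: Path) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class TiffDeflateCodec(LosslessCodec):
    """Multi-page TIFF with zlib/deflate compression (default codec)."""

    extension = ".tiff"

    def write(self, path: Path, frames: np.ndarray) -> None:
        tifffile.imwrite(path, frames, compression="zlib", photometric="minisblack")

    def read(self, path: Path) -> np.ndarray:
        return tifffile.imread(path)


def save_raw(scan: RawHSScan, path: str | Path,
             codec: LosslessCodec | None = None) -> Path:
    """Persist a raw scan (container + ``<stem>.json`` scan info).

    Returns the container path.  The achieved compression ratio versus the
    in-memory 16-bit stack is logged.
    """
    codec = codec if codec is not None else TiffDeflateCodec()
    path = Path(path)
    if path.suffix == "":
        path = path.with_suffix(codec.extension)
    path.parent.mkdir(parents=True, exist_ok=True)
    codec.write(path, scan.frames)
    info_path = path.with_suffix(".json")
    info_path.write_text(scan.info.to_json())
    raw_bytes = scan.frames.nbytes
    stored = path.stat().st_size
    if stored > 0:
        log.info("raw scan %s: %.2f:1 compression (%d -> %d bytes)",
                 path.name, raw_bytes / stored, raw_bytes, stored)
    return path


def load_raw(path: str | Path, codec: LosslessCodec | None = None) -> RawHSScan:
    """Load a raw scan saved by :func:`save_raw` (bit-exact)."""
    codec = codec if codec is not None else TiffDeflateCodec()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frames = codec.read(path)
    except Exception as exc:
        raise IOError(f"corrupt or unreadable raw container {path}: {exc}") from exc
    info_path = path.with_suffix(".json")
    if not info_path.exists():
        raise IOError(f"missing scan info sidecar {info_path}")
    info = ScanInfoRecord.from_json(info_path.read_text())
    if frames.ndim == 2:
        frames = frames[None]
    return RawHSScan(frames=frames, info=info)
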