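"""ROI label files and the automatic capture sequence.

A pathologist labels rectangular regions of interest on the whole-slide
image; each label carries the top-left pixel, size, histology class name,
a running index per class and the magnification used for the WS scan.
Label pixel coordinates refer to the reduced-resolution WS view whose
pixel size on the sample is M × Px μm (M = WS magnification, Px = RGB
pixel pitch), which makes the ROI-center conversion to stage μm exact.

The automatic sequence loops over the labels: move the stage to the ROI
center, autofocus, save an RGB snapshot, and run a minimum-length HS scan
into a folder named ``<histology>_<index>``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import tifffile

from . import geometry, hs_acquisition
from .autofocus import autofocus as run_autofocus
from .specs import AreaSensorSpec, WedgeSensorSpec

__all__ = [
    "ROILabel",
    "CaptureTask",
    "LabelValidationError",
    "read_labels",
    "write_labels",
    "make_ws_info",
    "plan_sequence",
    "run_sequence",
]

log = logging.getLogger(__name__)

REQUIRED_FIELDS = ("top_left_px", "width_px", "height_px",
                   "histology_class", "index", "ws_magnification")


class LabelValidationError(ValueError):
    """A label record is missing or violates a required field."""


@dataclass
class ROILabel:
    """One labeled region of interest on the whole-slide view."""

    top_left_px: tuple[float, float]      # (ROIx, ROIy)
    width_px: float
    height_px: float
    histology_class: str
    index: int                            # e.g. the fourth tumor labeled
    ws_magnification: float
    extras: dict = field(default_factory=dict)   # unknown fields, preserved

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise LabelValidationError("ROI width and height must be positive")
        if self.index < 1:
            raise LabelValidationError("label index must be >= 1")
        if not self.histology_class:
            raise LabelValidationError("histology class must be non-empty")

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.top_left_px[0] + self.width_px / 2.0,
                self.top_left_px[1] + self.height_px / 2.0)

    def to_dict(self) -> dict:
        d = {
            "top_left_px": list(self.top_left_px),
            "width_px": self.width_px,
            "height_px": self.height_px,
            "histology_class": self.histology_class,
            "index": self.index,
            "ws_magnification": self.ws_magnification,
        }
        d.update(self.extras)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ROILabel":
        missing = [k for k in REQUIRED_FIELDS if k not in d]
        if missing:
            raise LabelValidationError(f"label record missing field(s): {', '.join(missing)}")
        extras = {k: v for k, v in d.items() if k not in REQUIRED_FIELDS}
        return cls(
            top_left_px=tuple(d["top_left_px"]),
            width_px=d["width_px"],
            height_px=d["height_px"],
            histology_class=d["histology_class"],
            index=d["index"],
            ws_magnification=d["ws_magnification"],
            extras=extras,
        )


def write_labels(labels: list[ROILabel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([lb.to_dict() for lb in labels], indent=2))


def read_labels(path: str | Path) -> list[ROILabel]:
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list):
        raise LabelValidationError("label file must contain a JSON list")
    return [ROILabel.from_dict(r) for r in records]


def make_ws_info(grid, mag_factor: float, rgb: AreaSensorSpec) -> dict:
    """WS scan-information record for sequence planning: the scan origin
    (first tile center), the WS magnification, and the label-view bounds
    (the region corners mapped into the reduced-resolution view)."""
    origin = grid.origin_um
    corners_px = [
        geometry.stage_to_roi_center(origin, grid.stage_position(r, c), rgb, mag_factor)
        for r in (0, grid.n_rows - 1) for c in (0, grid.n_cols - 1)
    ]
    xs = [p[0] for p in corners_px]
    ys = [p[1] for p in corners_px]
    margin_x = rgb.height_px / 2.0
    margin_y = rgb.width_px / 2.0
    return {
        "origin_um": list(origin),
        "magnification": mag_factor,
        "n_cols": grid.n_cols,
        "n_rows": grid.n_rows,
        "view_bounds_px": [min(xs) - margin_x, min(ys) - margin_y,
                           max(xs) + margin_x, max(ys) + margin_y],
    }


@dataclass
class CaptureTask:
    """One planned HS + RGB capture centered on a labeled ROI."""

    label: ROILabel
    stage_target_um: tuple[float, float]
    capture_magnification: float
    n_frames: int
    output_folder: str

    @classmethod
    def folder_for(cls, label: ROILabel) -> str:
        return f"{label.histology_class}_{label.index}"


def plan_sequence(labels: list[ROILabel], ws_info: dict, target_mag: float,
                  rgb: AreaSensorSpec, wedge: WedgeSensorSpec) -> list[CaptureTask]:
    """One capture task per label, in label order.

    The stage target comes from the ROI-center conversion; the HS frame
    count is the minimum full-coverage count (432 for the physical sensor).
    Labels outside the WS view bounds are skipped with a warning.
    """
    if "origin_um" not in ws_info or "magnification" not in ws_info:
        raise ValueError("ws_info must record the scan origin and magnification")
    origin = tuple(ws_info["origin_um"])
    ws_mag = float(ws_info["magnification"])
    bounds = ws_info.get("view_bounds_px")
    n_frames = geometry.min_scan_frames(wedge)
    tasks = []
    for lb in labels:
        if bounds is not None:
            x0, y0 = lb.top_left_px
            x1, y1 = x0 + lb.width_px, y0 + lb.height_px
            if not (bounds[0] <= x0 and bounds[1] <= y0
                    and x1 <= bounds[2] and y1 <= bounds[3]):
                log.warning("label %s_%d lies outside the WS view; skipped",
                            lb.histology_class, lb.index)
                continue
        target = geometry.roi_center_to_stage(
            origin, lb.top_left_px, (lb.width_px, lb.height_px), rgb, ws_mag)
        tasks.append(CaptureTask(
            label=lb,
            stage_target_um=target,
            capture_magnification=target_mag,
            n_frames=n_frames,
            output_folder=CaptureTask.folder_for(lb),
        ))
    return tasks


def run_sequence(microscope, tasks: list[CaptureTask], work_dir: str | Path,
                 wedge: WedgeSensorSpec | None = None) -> list[dict]:
    """Execute the automatic sequence: per task, move → autofocus → RGB
    snapshot → minimum-length HS scan, all saved under the task folder.

    A failing task is recorded and isolated; the sequence continues with
    the next label.  Returns one manifest dict per task.
    """
    wedge = wedge if wedge is not None else microscope.system.wedge
    work_dir = Path(work_dir)
    manifests = []
    for task in tasks:
        folder = work_dir / task.output_folder
        # manifest paths are relative to work_dir, keeping same-seed runs
        # byte-identical regardless of the output location
        manifest: dict = {"label": task.label.to_dict(),
                          "stage_target_um": list(task.stage_target_um),
                          "folder": task.output_folder}
        try:
            folder.mkdir(parents=True, exist_ok=True)
            mag = microscope.system.magnification(task.capture_magnification)
            microscope.move_to(x_um=task.stage_target_um[0], y_um=task.stage_target_um[1])
            trace = run_autofocus(microscope, mag)
            manifest["autofocus"] = trace.to_json_records()
            if trace.error:
                raise RuntimeError(f"autofocus failed: {trace.error}")

            snapshot = microscope.capture_rgb(mag.factor)
            rgb_path = folder / "rgb_snapshot.tiff"
            tifffile.imwrite(rgb_path, snapshot)
            manifest["rgb_snapshot"] = f"{task.output_folder}/rgb_snapshot.tiff"

            plan = hs_acquisition.plan_hs_scan(
                wedge, mag, task.n_frames,
                microscope.pose.snapped(x_um=task.stage_target_um[0],
                                        y_um=task.stage_target_um[1]))
            scan = hs_acquisition.run_hs_scan(
                microscope, plan,
                sample_id=task.output_folder, mag=mag, spec=wedge)
            hs_acquisition.save_raw(scan, folder / "raw_scan.tiff")
            manifest["raw_scan"] = f"{task.output_folder}/raw_scan.tiff"
            manifest["n_frames"] = scan.n_frames
            manifest["status"] = "ok"
        except Exception as exc:
            manifest["status"] = "failed"
            manifest["error"] = str(exc)
            log.error("task %s failed: %s", task.output_folder, exc)
        (folder / "manifest.json").write_text(json.dumps(manifest, indent=2))
        manifests.append(manifest)
    return manifests
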