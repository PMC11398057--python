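"""Deterministic scan mathematics.

Everything here is closed-form arithmetic on the hardware specs: fields of
view, the per-frame stage step of a wedge scan, cube sizing, the
pixel↔stage coordinate maps used when the operator selects a region on an
overview image, the half-overlap tile grid of a whole-slide scan, and the
ROI-center conversion used by the automatic capture sequence.

Conventions
-----------
* Pixel coordinates are 0-based with the origin at the top-left.
* Stage coordinates are in μm.  No assumption is made that the top-left
  stage coordinate is numerically smaller than the bottom-right one; the
  overview map (``region_to_stage``) is sign-agnostic.
* Both cameras are mounted rotated 90° with respect to the stage, so image
  *rows* run along stage X and image *columns* along stage Y.  This is why
  the tile-grid column count pairs with the *vertical* FOV and why the ROI
  conversion swaps the sensor width and height between the axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .specs import AreaSensorSpec, MagnificationSpec, WedgeSensorSpec

__all__ = [
    "OverviewImageFrame",
    "TileGrid",
    "field_of_view",
    "step_distance",
    "min_scan_frames",
    "cube_vertical_resolution",
    "scan_length_um",
    "region_to_stage",
    "stage_to_region",
    "tile_grid",
    "roi_center_to_stage",
    "stage_to_roi_center",
]


def field_of_view(sensor: AreaSensorSpec | WedgeSensorSpec,
                  mag: MagnificationSpec | float) -> tuple[float, float]:
    """Physical field of view (horizontal, vertical) in μm.

    FOV per axis = sensor extent in pixels × pixel pitch / magnification.
    """
    factor = mag.factor if isinstance(mag, MagnificationSpec) else float(mag)
    if factor <= 0:
        raise ValueError("magnification must be positive")
    return (
        sensor.width_px * sensor.pixel_pitch_um / factor,
        sensor.height_px * sensor.pixel_pitch_um / factor,
    )


def step_distance(spec: WedgeSensorSpec, mag: MagnificationSpec | float) -> float:
    """Stage displacement *d* between consecutive wedge frames, in μm.

    d = FOVv × hband / h — the full-sensor vertical FOV scaled by the
    fraction of the sensor one band occupies; equivalently one band height
    projected to the sample: band_height_px × pitch / magnification.
    """
    factor = mag.factor if isinstance(mag, MagnificationSpec) else float(mag)
    if factor <= 0:
        raise ValueError("magnification must be positive")
    fov_v = spec.height_px * spec.pixel_pitch_um / factor
    return fov_v * spec.band_height_px / spec.height_px


def min_scan_frames(spec: WedgeSensorSpec) -> int:
    """Minimum number of frames for full spectral coverage: twice the
    number of theoretical bands."""
    return 2 * spec.n_theoretical_bands


def cube_vertical_resolution(spec: WedgeSensorSpec, n_frames: int) -> int:
    """Vertical (row) resolution in pixels of the cube composed from a scan
    of ``n_frames`` frames: (Nf − n_bands) × band height."""
    n_min = min_scan_frames(spec)
    if n_frames < n_min:
        raise ValueError(
            f"n_frames={n_frames} is below the minimum {n_min} "
            f"(= 2 x {spec.n_theoretical_bands} theoretical bands)"
        )
    return (n_frames - spec.n_theoretical_bands) * spec.band_height_px


def scan_length_um(spec: WedgeSensorSpec, n_frames: int,
                   mag: MagnificationSpec | float) -> float:
    """Physical length covered by an HS scan of ``n_frames`` frames."""
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    return n_frames * step_distance(spec, mag)


@dataclass
class OverviewImageFrame:
    """A low-resolution overview image of the slide whose corners have known
    stage coordinates, used by the operator to pick a scan region."""

    width_px: int
    height_px: int
    top_left_stage_um: tuple[float, float]
    bottom_right_stage_um: tuple[float, float]

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("overview frame dimensions must be positive")
        tl, br = self.top_left_stage_um, self.bottom_right_stage_um
        if tl[0] == br[0] or tl[1] == br[1]:
            raise ValueError("top-left and bottom-right stage corners must differ in both axes")


def region_to_stage(frame: OverviewImageFrame, rx_px: float, ry_px: float) -> tuple[float, float]:
    """Map overview-image pixel coordinates to stage μm.

    Per axis: O = (TL − BR) × (1 − R/dim) + BR.  The end point of a region
    (Rx+Rw, Ry+Rh) is this same map applied to the opposite corner.
    """
    if not (0 <= rx_px <= frame.width_px) or not (0 <= ry_px <= frame.height_px):
        raise ValueError(
            f"pixel ({rx_px}, {ry_px}) outside overview frame "
            f"{frame.width_px} x {frame.height_px}"
        )
    tlx, tly = frame.top_left_stage_um
    brx, bry = frame.bottom_right_stage_um
    ox = (tlx - brx) * (1.0 - rx_px / frame.width_px) + brx
    oy = (tly - bry) * (1.0 - ry_px / frame.height_px) + bry
    return ox, oy


def stage_to_region(frame: OverviewImageFrame, x_um: float, y_um: float) -> tuple[float, float]:
    """Inverse of :func:`region_to_stage` (exact affine inverse)."""
    tlx, tly = frame.top_left_stage_um
    brx, bry = frame.bottom_right_stage_um
    rx = (1.0 - (x_um - brx) / (tlx - brx)) * frame.width_px
    ry = (1.0 - (y_um - bry) / (tly - bry)) * frame.height_px
    return rx, ry


@dataclass
class TileGrid:
    """Whole-slide scan plan: a grid of half-overlapping RGB fields visited
    in a snake (boustrophedon) order."""

    n_cols: int
    n_rows: int
    origin_um: tuple[float, float]
    end_um: tuple[float, float]
    col_step_um: float
    row_step_um: float
    snake_order: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return self.n_cols * self.n_rows

    def stage_position(self, row: int, col: int) -> tuple[float, float]:
        """Stage center of tile (row, col).  Columns advance along stage X
        (signed toward the end point), rows along stage Y."""
        ox, oy = self.origin_um
        return ox + col * self.col_step_um, oy + row * self.row_step_um


def tile_grid(origin_um: tuple[float, float], end_um: tuple[float, float],
              rgb_fov: tuple[float, float]) -> TileGrid:
    """Build the half-overlap whole-slide tile grid between two stage points.

    Nc = ceil(|Ox − Fx| / (FOVv/2)) columns along stage X and
    Nr = ceil(|Oy − Fy| / (FOVh/2)) rows along stage Y; the ceiling keeps the
    region fully covered.  Because the camera is rotated 90°, the column
    count pairs with the *vertical* FOV.  Steps are signed toward the end
    point and are exactly half the corresponding FOV.
    """
    fov_h, fov_v = rgb_fov
    if fov_h <= 0 or fov_v <= 0:
        raise ValueError("FOV must be positive")
    ox, oy = origin_um
    fx, fy = end_um
    span_x, span_y = abs(ox - fx), abs(oy - fy)
    if span_x == 0 or span_y == 0:
        raise ValueError("degenerate (zero-area) scan region")
    n_cols = math.ceil(span_x / (fov_v / 2.0))
    n_rows = math.ceil(span_y / (fov_h / 2.0))
    col_step = math.copysign(fov_v / 2.0, fx - ox)
    row_step = math.copysign(fov_h / 2.0, fy - oy)
    order = []
    for r in range(n_rows):
        cols = range(n_cols) if r % 2 == 0 else range(n_cols - 1, -1, -1)
        order.extend((r, c) for c in cols)
    return TileGrid(
        n_cols=n_cols, n_rows=n_rows, origin_um=(ox, oy), end_um=(fx, fy),
        col_step_um=col_step, row_step_um=row_step, snake_order=order,
    )


def roi_center_to_stage(ws_origin_um: tuple[float, float],
                        roi_top_left_px: tuple[float, float],
                        roi_size_px: tuple[float, float],
                        rgb: AreaSensorSpec,
                        ws_mag: MagnificationSpec | float) -> tuple[float, float]:
    """Convert a labeled ROI's center to the stage target that centers the
    capture on it.

    X = Ox − ((ROIx + ROIw/2 − H/2) × M × Px)
    Y = Oy − ((ROIy + ROIh/2 − W/2) × M × Px)

    The sensor height H enters the X axis and the width W the Y axis — the
    axis swap caused by the 90° camera rotation — and is preserved exactly.
    ROI pixel coordinates refer to the reduced-resolution whole-slide view
    whose pixel size on the sample is M × Px μm.
    """
    factor = ws_mag.factor if isinstance(ws_mag, MagnificationSpec) else float(ws_mag)
    ox, oy = ws_origin_um
    roi_x, roi_y = roi_top_left_px
    roi_w, roi_h = roi_size_px
    scale = factor * rgb.pixel_pitch_um
    x = ox - (roi_x + roi_w / 2.0 - rgb.height_px / 2.0) * scale
    y = oy - (roi_y + roi_h / 2.0 - rgb.width_px / 2.0) * scale
    return x, y


def stage_to_roi_center(ws_origin_um: tuple[float, float],
                        stage_um: tuple[float, float],
                        rgb: AreaSensorSpec,
                        ws_mag: MagnificationSpec | float) -> tuple[float, float]:
    """Inverse of :func:`roi_center_to_stage`: the reduced-resolution WS-view
    pixel under a stage position (returns the ROI *center* in px)."""
    factor = ws_mag.factor if isinstance(ws_mag, MagnificationSpec) else float(ws_mag)
    ox, oy = ws_origin_um
    scale = factor * rgb.pixel_pitch_um
    cx = (ox - stage_um[0]) / scale + rgb.height_px / 2.0
    cy = (oy - stage_um[1]) / scale + rgb.width_px / 2.0
    return cx, cy
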