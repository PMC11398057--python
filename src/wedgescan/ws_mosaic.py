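"""Whole-slide RGB scanning and stitching.

Tiles are captured on a half-overlap snake grid, flat-field corrected by an
empty-slide white image, and registered pairwise: SIFT keypoints detected
in the overlapping halves, matched exhaustively (mutual best matches), and
a robust affine fitted by random-sample consensus with a least-squares
refit on the inliers.  Rows are composed by chaining the within-row
transforms; composed row strips are then registered to each other the same
way and merged into the final canvas.  A naive tiling baseline (tiles
placed at nominal positions without overlap or correction) is provided for
comparison.

Because every capture shares the camera orientation, the pairwise
transforms are near-pure translations; the camera-to-stage mount rotation
shows up as the angle between the measured translation vector and the
nominal grid step (see :meth:`PairwiseAffine.implied_rotation_deg`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import AffineTransform, EuclideanTransform, warp

from .geometry import TileGrid

__all__ = [
    "TileStack",
    "PairwiseAffine",
    "MosaicResult",
    "LowTextureError",
    "run_ws_scan",
    "flat_field",
    "estimate_pair_affine",
    "compose_mosaic",
    "compose_tiling_baseline",
    "plan_tiling_grid",
    "ncc",
]

log = logging.getLogger(__name__)

FEATHER_PX = 16
SCALE_BOUNDS = (0.98, 1.02)
RANSAC_RESIDUAL_PX = 3.0
MAX_PAIR_ROTATION_DEG = 2.0     # mount misalignment is bounded by the physics
MAX_PAIR_DEVIATION_PX = 16.0    # max drift of a fit from the nominal grid step
MIN_PAIR_INLIERS = 5


class LowTextureError(RuntimeError):
    """Raised when an overlap yields too few keypoint matches for a fit."""


@dataclass
class TileStack:
    """Captured WS tiles in snake order plus the scan context."""

    tiles: list[np.ndarray]
    grid: TileGrid
    white_image: np.ndarray | None = None
    scan_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.tiles) != self.grid.n_total:
            raise ValueError("tile count does not match the grid")
        shapes = {t.shape for t in self.tiles}
        if len(shapes) > 1:
            raise ValueError("all tiles must share a shape")

    def by_grid(self) -> dict[tuple[int, int], np.ndarray]:
        """Tiles keyed by (row, col), undoing the snake capture order."""
        return dict(zip(self.grid.snake_order, self.tiles))


@dataclass
class PairwiseAffine:
    """Registration of image b into image a's pixel frame."""

    matrix: np.ndarray            # 2x3, maps b (row, col) -> a (row, col)
    n_matches: int
    inlier_fraction: float
    direction: str                # "vertical" | "horizontal"
    fallback: bool = False        # nominal translation used instead of a fit

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    @property
    def rotation_deg(self) -> float:
        """In-plane rotation of the linear part (≈ 0 for same-camera pairs)."""
        return float(np.degrees(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    def implied_rotation_deg(self, nominal_offset_px: tuple[float, float]) -> float:
        """Camera-to-stage mount rotation implied by this pair: the signed
        angle between the measured translation and the nominal grid step."""
        t = self.translation
        n = np.asarray(nominal_offset_px, dtype=float)
        cross = n[0] * t[1] - n[1] * t[0]
        dot = float(n @ t)
        return float(np.degrees(np.arctan2(cross, dot)))


def run_ws_scan(microscope, grid: TileGrid, mag_factor: float,
                sensor=None) -> TileStack:
    """Capture every grid tile in snake order plus the white image.

    Poses outside the phantom are rejected at planning time, before any
    capture is taken.
    """
    ex, ey = microscope.phantom.extent_um
    for r, c in grid.snake_order:
        x, y = grid.stage_position(r, c)
        if not (0 <= x <= ex and 0 <= y <= ey):
            raise ValueError(f"tile ({r}, {c}) at ({x:.0f}, {y:.0f}) um is outside the phantom")
    microscope.lock_manual_controls()
    try:
        tiles = []
        for r, c in grid.snake_order:
            x, y = grid.stage_position(r, c)
            microscope.move_to(x_um=x, y_um=y)
            tiles.append(microscope.capture_rgb(mag_factor, sensor))
        white = microscope.capture_rgb_white(mag_factor, sensor)
    finally:
        microscope.release_manual_controls()
    info = {
        "magnification": mag_factor,
        "n_cols": grid.n_cols,
        "n_rows": grid.n_rows,
        "n_total": grid.n_total,
        "origin_um": list(grid.origin_um),
        "end_um": list(grid.end_um),
        "col_step_um": grid.col_step_um,
        "row_step_um": grid.row_step_um,
    }
    return TileStack(tiles=tiles, grid=grid, white_image=white, scan_info=info)


def flat_field(tile: np.ndarray, white_image: np.ndarray) -> np.ndarray:
    """Divide a capture by the empty-slide white image to remove vignetting
    and illumination non-uniformity, rescaled back to the input range.

    Zero-valued white pixels carry no information; they are flagged (logged)
    and output 0 there.
    """
    tile = np.asarray(tile, dtype=float)
    white = np.asarray(white_image, dtype=float)
    if tile.shape != white.shape:
        raise ValueError("tile and white image must share a shape")
    bad = white == 0
    if bad.any():
        log.warning("flat_field: %d zero-valued white pixels flagged", int(bad.sum()))
    ratio = np.zeros_like(tile)
    np.divide(tile, white, out=ratio, where=~bad)
    return ratio * white.max()


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    return img.mean(axis=-1) if img.ndim == 3 else img


def _normalize(img: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1] so SIFT's absolute DoG thresholds behave the same
    regardless of sensor bit depth."""
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)


def _overlap_halves(img_a: np.ndarray, img_b: np.ndarray, direction: str
                    ) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Crop the overlapping halves; returns (half_a, half_b, a_crop_offset).

    "vertical": b sits half a FOV further along image rows (a's bottom half
    overlaps b's top half).  "horizontal": along image columns.
    """
    h, w = img_a.shape[:2]
    if direction == "vertical":
        return img_a[h // 2:], img_b[: h - h // 2], (h // 2, 0.0)
    if direction == "horizontal":
        return img_a[:, w // 2:], img_b[:, : w - w // 2], (0.0, w // 2)
    if direction == "full":
        return img_a, img_b, (0.0, 0.0)
    raise ValueError(f"unknown direction {direction!r}")


def _nominal_offset_px(shape: tuple[int, ...], direction: str) -> tuple[float, float]:
    if direction == "vertical":
        return (shape[0] / 2.0, 0.0)
    if direction == "horizontal":
        return (0.0, shape[1] / 2.0)
    return (0.0, 0.0)


def estimate_pair_affine(img_a: np.ndarray, img_b: np.ndarray, direction: str,
                         seed: int = 0,
                         nominal_offset_px: tuple[float, float] | None = None
                         ) -> PairwiseAffine:
    """Register ``img_b`` into ``img_a``'s frame via their overlap halves.

    SIFT keypoints and descriptors are computed only on the overlapping
    halves, matched exhaustively keeping mutual best matches, and an affine
    is fitted by random-sample consensus (3 px inlier threshold) with a
    least-squares refit on the inliers.  The scale component is constrained
    to [0.98, 1.02]; outside that range the fit is redone as a rigid
    (rotation + translation) transform.  Transforms that are numerically an
    integer translation snap to it exactly.
    """
    gray_a, gray_b = _to_gray(img_a), _to_gray(img_b)
    half_a, half_b, a_off = _overlap_halves(gray_a, gray_b, direction)

    detector_a, detector_b = SIFT(c_dog=0.005), SIFT(c_dog=0.005)
    try:
        detector_a.detect_and_extract(_normalize(half_a))
        detector_b.detect_and_extract(_normalize(half_b))
    except RuntimeError as exc:  # no keypoints found at all
        raise LowTextureError(f"SIFT found no keypoints in overlap: {exc}") from exc
    matches = match_descriptors(detector_b.descriptors, detector_a.descriptors,
                                cross_check=True)
    if matches.shape[0] < 3:
        raise LowTextureError(
            f"only {matches.shape[0]} usable matches in {direction} overlap")

    src = detector_b.keypoints[matches[:, 0]].astype(float)          # b half coords
    dst = detector_a.keypoints[matches[:, 1]].astype(float) + a_off  # a full coords

    # consensus on a rigid model (the physics allows only rotation +
    # translation drift), then a least-squares affine refit on the inliers
    model, inliers = ransac(
        (src, dst), EuclideanTransform, min_samples=2,
        residual_threshold=RANSAC_RESIDUAL_PX, max_trials=1000,
        rng=np.random.default_rng(seed),
    )
    if model is None or inliers is None or inliers.sum() < MIN_PAIR_INLIERS:
        raise LowTextureError("consensus rigid fit failed on overlap matches")
    refit = AffineTransform.from_estimate(src[inliers], dst[inliers])
    if not refit or not all(SCALE_BOUNDS[0] <= s <= SCALE_BOUNDS[1]
                            for s in np.atleast_1d(refit.scale)):
        rigid = EuclideanTransform.from_estimate(src[inliers], dst[inliers])
        if not rigid:
            raise LowTextureError("degenerate refit on overlap inliers")
        refit = AffineTransform(matrix=rigid.params)

    # keypoints were fed as (row, col) pairs, so the fitted params already
    # form the (row, col) affine
    matrix = refit.params[:2].copy()
    matrix = _refine_translation(matrix, half_a, half_b, a_off)
    matrix = _snap_integer(matrix)
    pair = PairwiseAffine(
        matrix=matrix,
        n_matches=int(matches.shape[0]),
        inlier_fraction=float(inliers.mean()),
        direction=direction,
    )
    # physical sanity: the mount rotation is a few tenths of a degree and
    # the stage places tiles within a few px of the nominal half-FOV step;
    # a "fit" outside those bounds is a spurious consensus on repetitive
    # texture, and the caller should fall back to nominal placement
    if nominal_offset_px is None:
        nominal_offset_px = _nominal_offset_px(gray_a.shape, direction)
    nominal = np.asarray(nominal_offset_px)
    if (abs(pair.rotation_deg) > MAX_PAIR_ROTATION_DEG
            or np.linalg.norm(pair.translation - nominal) > MAX_PAIR_DEVIATION_PX):
        raise LowTextureError(
            f"fit deviates from nominal placement by "
            f"{np.linalg.norm(pair.translation - nominal):.1f} px "
            f"(rotation {pair.rotation_deg:.2f} deg); treating as low texture")
    return pair


LIN_IDENTITY_TOL = 0.01   # ~0.57 deg rotation / 1% scale


def _subpixel_shift(ref: np.ndarray, moving: np.ndarray,
                    start: np.ndarray, radius: float = 1.5) -> np.ndarray | None:
    """Shift registering ``moving`` to ``ref`` by direct SSD minimization
    with cubic-spline interpolation, searched within ``radius`` px of
    ``start``.  Returns None when the optimum hits the search boundary."""
    from scipy import ndimage, optimize

    filtered = ndimage.spline_filter(moving, order=3)
    crop = 8

    def ssd(s):
        if np.abs(s - start).max() > radius:
            return np.inf
        shifted = ndimage.shift(filtered, s, order=3, prefilter=False)
        diff = ref[crop:-crop, crop:-crop] - shifted[crop:-crop, crop:-crop]
        return float(np.sum(diff * diff))

    res = optimize.minimize(ssd, start, method="Nelder-Mead",
                            options={"xatol": 0.005, "fatol": 1e-3})
    if not np.isfinite(res.fun) or np.abs(res.x - start).max() > radius - 0.05:
        return None
    return res.x


def _refine_translation(matrix: np.ndarray, half_a: np.ndarray,
                        half_b: np.ndarray, a_off: tuple[float, float],
                        max_residual_px: float = 3.0) -> np.ndarray:
    """Pin the fitted translation to sub-pixel precision.

    Keypoint localization limits the SIFT fit to a few tenths of a pixel;
    direct SSD matching of the overlap halves (seeded by the keypoint fit)
    measures their mean relative shift more precisely.  Because every
    capture shares the camera mount, a linear part within
    ``LIN_IDENTITY_TOL`` of the identity is spurious keypoint noise and is
    projected onto the identity, keeping the displacement it implied at the
    patch centroid.  An SSD optimum inconsistent with the keypoint fit is
    distrusted and the keypoint fit kept.
    """
    h = min(half_a.shape[0], half_b.shape[0])
    w = min(half_a.shape[1], half_b.shape[1])
    centroid_b = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    lin = matrix[:, :2]
    t = matrix[:, 2]
    if np.abs(lin - np.eye(2)).max() < LIN_IDENTITY_TOL:
        t = (lin - np.eye(2)) @ centroid_b + t
        lin = np.eye(2)
    # relative shift of the halves implied by the current fit, then refined
    start = (lin @ centroid_b + t) - np.asarray(a_off) - centroid_b
    shift = _subpixel_shift(half_a[:h, :w], half_b[:h, :w], start)
    if shift is None:
        return np.hstack([lin, t[:, None]])
    target = centroid_b + shift + np.asarray(a_off)
    refined_t = target - lin @ centroid_b
    if np.linalg.norm(refined_t - t) > max_residual_px:
        return np.hstack([lin, t[:, None]])
    return np.hstack([lin, refined_t[:, None]])


def _snap_integer(matrix: np.ndarray, lin_tol: float = 1e-4,
                  trans_tol: float = 0.1) -> np.ndarray:
    """Snap a near-identity-plus-integer-translation matrix to exactness so
    that noiseless pipelines stay bit-exact."""
    lin = matrix[:, :2]
    t = matrix[:, 2]
    if (np.abs(lin - np.eye(2)).max() < lin_tol
            and np.abs(t - np.round(t)).max() < trans_tol):
        out = np.hstack([np.eye(2), np.round(t)[:, None]])
        return out
    return matrix


def _nominal_pair(shape: tuple[int, ...], direction: str) -> PairwiseAffine:
    off = _nominal_offset_px(shape, direction)
    return PairwiseAffine(
        matrix=np.array([[1.0, 0.0, off[0]], [0.0, 1.0, off[1]]]),
        n_matches=0, inlier_fraction=0.0, direction=direction, fallback=True,
    )


def _compose(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Compose two 2×3 (row, col) affines: result applies b then a."""
    ra = np.vstack([a, [0.0, 0.0, 1.0]])
    rb = np.vstack([b, [0.0, 0.0, 1.0]])
    return (ra @ rb)[:2]


def _is_integer_translation(matrix: np.ndarray) -> bool:
    return (np.array_equal(matrix[:, :2], np.eye(2))
            and np.array_equal(matrix[:, 2], np.round(matrix[:, 2])))


def _feather_weight(h: int, w: int) -> np.ndarray:
    """Blend weight ramping from 1/FEATHER_PX at the tile border to 1 over a
    FEATHER_PX-wide band (power-of-two steps keep blending of identical
    content bit-exact)."""
    rr = np.minimum(np.arange(h), np.arange(h)[::-1])
    cc = np.minimum(np.arange(w), np.arange(w)[::-1])
    return np.minimum(
        np.clip((rr[:, None] + 1) / FEATHER_PX, 0, 1),
        np.clip((cc[None, :] + 1) / FEATHER_PX, 0, 1),
    )


def _paste(canvas: np.ndarray, filled: np.ndarray, img: np.ndarray,
           matrix: np.ndarray) -> None:
    """Place ``img`` on the canvas under a (row, col) affine: last written
    wins, blended with the existing content over a feathered border band.
    Exact integer translations are pasted without interpolation."""
    h, w = img.shape[:2]
    img = np.asarray(img, dtype=float)
    weight = _feather_weight(h, w)
    if _is_integer_translation(matrix):
        r0, c0 = int(matrix[0, 2]), int(matrix[1, 2])
        sub_c = canvas[r0:r0 + h, c0:c0 + w]
        sub_f = filled[r0:r0 + h, c0:c0 + w]
        blend = np.where(sub_f, weight, 1.0)
        sub_c[...] = blend[..., None] * img + (1.0 - blend[..., None]) * sub_c
        sub_f[...] = True
        return
    # general path: warp the tile (and its feather weights) onto the canvas
    m_rc = np.vstack([matrix, [0.0, 0.0, 1.0]])
    swap = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    tf = AffineTransform(matrix=swap @ m_rc @ swap)  # skimage works in (x, y)
    out_shape = canvas.shape[:2]
    warped = np.stack(
        [warp(img[..., ch], tf.inverse, output_shape=out_shape, order=1,
              mode="constant", cval=-1.0, preserve_range=True)
         for ch in range(img.shape[2])], axis=-1)
    valid = np.all(warped >= 0.0, axis=-1)
    warped = np.clip(warped, 0.0, None)
    w_warp = warp(weight, tf.inverse, output_shape=out_shape, order=1,
                  mode="constant", cval=0.0, preserve_range=True)
    blend = np.where(filled, w_warp, 1.0)
    canvas[valid] = (blend[valid, None] * warped[valid]
                     + (1.0 - blend[valid, None]) * canvas[valid])
    filled |= valid


@dataclass
class MosaicResult:
    """Stitched whole-slide image plus the registration bookkeeping."""

    image: np.ndarray
    pair_transforms: dict
    tile_transforms: dict
    composition_log: list[str]
    nominal_shape: tuple[int, int]
    covered_shape: tuple[int, int]

    def implied_rotation_deg(self) -> float:
        """Mount rotation implied by the fitted pairs (mean over non-fallback
        within-row and row-to-row pairs)."""
        angles = [p.implied_rotation_deg(p._nominal)  # type: ignore[attr-defined]
                  for p in self.pair_transforms.values()
                  if not p.fallback and hasattr(p, "_nominal")]
        if not angles:
            return 0.0
        return float(np.mean(angles))


def compose_mosaic(stack: TileStack, seed: int = 0,
                   apply_flat_field: bool = True) -> MosaicResult:
    """Stitch a half-overlap tile stack.

    Within each grid row the pairwise transforms are chained; each composed
    row strip is then registered to the previous strip and the canvas is
    assembled with feathered last-written-wins blending.  Any failed pair
    falls back to the nominal half-FOV translation and is recorded in the
    composition log.
    """
    tiles = stack.by_grid()
    if apply_flat_field and stack.white_image is not None:
        tiles = {k: flat_field(v, stack.white_image) for k, v in tiles.items()}
    else:
        tiles = {k: np.asarray(v, dtype=float) for k, v in tiles.items()}
    some_tile = next(iter(tiles.values()))
    th, tw = some_tile.shape[:2]
    n_rows, n_cols = stack.grid.n_rows, stack.grid.n_cols
    logbook: list[str] = []
    pairs: dict = {}

    def estimate(a, b, direction, key):
        try:
            pair = estimate_pair_affine(a, b, direction, seed=seed)
        except LowTextureError as exc:
            pair = _nominal_pair(a.shape, direction)
            logbook.append(f"pair {key}: fallback to nominal placement ({exc})")
        pair._nominal = _nominal_offset_px(a.shape, direction)  # noqa: SLF001
        pairs[key] = pair
        return pair

    # within-row chains and strip composition
    strips = []
    strip_tile_transforms: list[dict] = []
    for r in range(n_rows):
        transforms = {0: np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])}
        for c in range(1, n_cols):
            pair = estimate(tiles[(r, c - 1)], tiles[(r, c)], "vertical", (r, c - 1, r, c))
            transforms[c] = _compose(transforms[c - 1], pair.matrix)
        extent = _canvas_extent(transforms.values(), (th, tw))
        shift = np.array([[1.0, 0.0, -extent[0]], [0.0, 1.0, -extent[1]]])
        transforms = {c: _compose(shift, m) for c, m in transforms.items()}
        strip = np.zeros((extent[2] - extent[0], extent[3] - extent[1],
                          some_tile.shape[2]))
        filled = np.zeros(strip.shape[:2], dtype=bool)
        for c in range(n_cols):
            _paste(strip, filled, tiles[(r, c)], transforms[c])
        strips.append(strip)
        strip_tile_transforms.append(transforms)

    # row-to-row chain over the composed strips
    strip_global = {0: np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])}
    for r in range(1, n_rows):
        pair = estimate(strips[r - 1], strips[r], "horizontal", ("strip", r - 1, r))
        strip_global[r] = _compose(strip_global[r - 1], pair.matrix)

    tile_transforms = {}
    all_ms = []
    for r in range(n_rows):
        for c in range(n_cols):
            m = _compose(strip_global[r], strip_tile_transforms[r][c])
            tile_transforms[(r, c)] = m
            all_ms.append(m)
    extent = _canvas_extent(all_ms, (th, tw))
    shift = np.array([[1.0, 0.0, -extent[0]], [0.0, 1.0, -extent[1]]])
    tile_transforms = {k: _compose(shift, m) for k, m in tile_transforms.items()}

    canvas = np.zeros((extent[2] - extent[0], extent[3] - extent[1],
                       some_tile.shape[2]))
    filled = np.zeros(canvas.shape[:2], dtype=bool)
    for r in range(n_rows):
        for c in range(n_cols):
            _paste(canvas, filled, tiles[(r, c)], tile_transforms[(r, c)])

    return MosaicResult(
        image=canvas,
        pair_transforms=pairs,
        tile_transforms=tile_transforms,
        composition_log=logbook,
        nominal_shape=(n_cols * th, n_rows * tw),
        covered_shape=canvas.shape[:2],
    )


def _canvas_extent(matrices, tile_shape) -> tuple[int, int, int, int]:
    """(min_row, min_col, max_row, max_col) over transformed tile corners."""
    h, w = tile_shape
    corners = np.array([[0.0, 0.0, 1], [h, 0, 1], [0, w, 1], [h, w, 1]]).T
    lo = np.array([np.inf, np.inf])
    hi = -np.array([np.inf, np.inf])
    for m in matrices:
        pts = np.vstack([m, [0, 0, 1]]) @ corners
        lo = np.minimum(lo, pts[:2].min(axis=1))
        hi = np.maximum(hi, pts[:2].max(axis=1))
    return (int(np.floor(lo[0])), int(np.floor(lo[1])),
            int(np.ceil(hi[0])), int(np.ceil(hi[1])))


def plan_tiling_grid(origin_um, end_um, rgb_fov) -> TileGrid:
    """No-overlap plan for the naive tiling baseline: same region, full-FOV
    steps (≈ a quarter as many tiles as the half-overlap plan)."""
    from . import geometry as _g
    grid = _g.tile_grid(origin_um, end_um, rgb_fov)
    n_cols = int(np.ceil(grid.n_cols / 2))
    n_rows = int(np.ceil(grid.n_rows / 2))
    order = []
    for r in range(n_rows):
        cols = range(n_cols) if r % 2 == 0 else range(n_cols - 1, -1, -1)
        order.extend((r, c) for c in cols)
    return TileGrid(
        n_cols=n_cols, n_rows=n_rows, origin_um=grid.origin_um, end_um=grid.end_um,
        col_step_um=grid.col_step_um * 2, row_step_um=grid.row_step_um * 2,
        snake_order=order,
    )


def compose_tiling_baseline(stack: TileStack,
                            apply_flat_field: bool = False) -> np.ndarray:
    """Place no-overlap tiles side by side at their nominal grid positions
    with no geometric correction."""
    tiles = stack.by_grid()
    if apply_flat_field and stack.white_image is not None:
        tiles = {k: flat_field(v, stack.white_image) for k, v in tiles.items()}
    else:
        tiles = {k: np.asarray(v, dtype=float) for k, v in tiles.items()}
    th, tw = next(iter(tiles.values())).shape[:2]
    n_rows, n_cols = stack.grid.n_rows, stack.grid.n_cols
    canvas = np.zeros((n_cols * th, n_rows * tw, next(iter(tiles.values())).shape[2]))
    for (r, c), tile in tiles.items():
        canvas[c * th:(c + 1) * th, r * tw:(r + 1) * tw] = tile
    return canvas


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation (Pearson) between two equal-shape images."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0
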