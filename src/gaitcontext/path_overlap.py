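"""Walking-path model and mask-based overlap detection.

The wearer's immediate forward path is modelled as a trapezoid anchored on
the bottom edge of the egocentric frame: wide at the base (the ground
directly in front of the feet), narrowing upward to mimic perspective
convergence.  Hazard contextualization then reduces to three binary-mask
intersections per frame:

* object mask ∧ path mask  → is the object in the immediate walking path?
* object mask ∧ gaze mask  → is the wearer looking at the object?

Masks are rasterized directly at a reduced resolution (default 200 × 200
cells) by coordinate scaling; a cell is set when its full-frame pixel
footprint intersects the shape (outward rounding).  This makes the
downscaled masks *supersets* of the exact shapes, so a genuinely
overlapping object/path pair can never be missed — disagreements with
full-resolution geometry are confined to near-misses thinner than one
cell, and the deliberate bias is toward false alarms, the cheaper error
when the subject is fall risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .core import BoundingBox, Detection, FrameRecord, GazeSample
from .taxonomy import Taxonomy, is_hazard_class

DEFAULT_MASK_RESOLUTION = (200, 200)
DEFAULT_GAZE_RADIUS = 30.0


@dataclass(frozen=True)
class PathConfig:
    """Trapezoid proportions as dimensionless fractions of the frame.

    ``base_width_fraction``: width of the base on the bottom frame row
    (default 0.50 — the middle 50% of the frame).
    ``top_width_fraction``: width of the (narrower) top edge.
    ``top_y_fraction``: vertical position of the top edge, as a fraction
    of frame height measured from the top.
    """

    base_width_fraction: float = 0.50
    top_width_fraction: float = 0.15
    top_y_fraction: float = 0.55

    def __post_init__(self) -> None:
        if not 0.0 < self.base_width_fraction <= 1.0:
            raise ValueError("base_width_fraction must be in (0, 1]")
        if not 0.0 < self.top_width_fraction <= 1.0:
            raise ValueError("top_width_fraction must be in (0, 1]")
        if not 0.0 <= self.top_y_fraction < 1.0:
            raise ValueError("top_y_fraction must be in [0, 1)")
        if self.top_width_fraction > self.base_width_fraction:
            raise ValueError(
                "top_width_fraction must not exceed base_width_fraction "
                "(perspective converges upward)"
            )


@dataclass(frozen=True)
class WalkingPath:
    """Trapezoid in pixel coordinates, vertices ordered
    bottom-left, bottom-right, top-right, top-left.  The bottom edge lies
    on the last frame row; the shape is symmetric about the vertical
    midline."""

    bottom_left: tuple[float, float]
    bottom_right: tuple[float, float]
    top_right: tuple[float, float]
    top_left: tuple[float, float]

    @property
    def vertices(self) -> tuple[tuple[float, float], ...]:
        return (self.bottom_left, self.bottom_right, self.top_right, self.top_left)

    @property
    def base_width(self) -> float:
        return self.bottom_right[0] - self.bottom_left[0]

    @property
    def top_y(self) -> float:
        return self.top_left[1]

    @property
    def bottom_y(self) -> float:
        return self.bottom_left[1]

    def x_extent_at(self, y: float) -> Optional[tuple[float, float]]:
        """Horizontal interval occupied by the trapezoid at height ``y``,
        or ``None`` outside its vertical span.  Linear in ``y`` between
        the top and bottom edges."""
        y0, y1 = self.top_y, self.bottom_y
        if y < y0 or y > y1:
            return None
        if y1 == y0:
            t = 1.0
        else:
            t = (y - y0) / (y1 - y0)
        left = self.top_left[0] + t * (self.bottom_left[0] - self.top_left[0])
        right = self.top_right[0] + t * (self.bottom_right[0] - self.top_right[0])
        return (left, right)


@dataclass(frozen=True)
class Circle:
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class BinaryMask:
    """A 0/1 grid covering the frame at reduced resolution.

    Cell (row, col) corresponds to the full-frame pixel footprint
    ``[col*sx, (col+1)*sx) x [row*sy, (row+1)*sy)`` where
    ``sx = frame_width / n_cols`` and ``sy = frame_height / n_rows``.
    """

    grid: np.ndarray  # uint8, shape (n_rows, n_cols)
    frame_width: float
    frame_height: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.uint8)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def resolution(self) -> tuple[int, int]:
        h, w = self.grid.shape
        return (w, h)

    @property
    def cell_size(self) -> tuple[float, float]:
        h, w = self.grid.shape
        return (self.frame_width / w, self.frame_height / h)

    def overlaps(self, other: "BinaryMask") -> bool:
        """True iff the bitwise AND of the two grids has any set cell."""
        if self.grid.shape != other.grid.shape:
            raise ValueError("mask resolutions differ")
        return bool(np.bitwise_and(self.grid, other.grid).any())


@dataclass(frozen=True)
class OverlapVerdict:
    detection: Detection
    in_path: bool
    gazed: bool


@dataclass
class FrameContext:
    """Frame-level hazard summary derived from per-object verdicts."""

    frame_index: int
    timestamp: float
    verdicts: list[OverlapVerdict]
    hazard_in_path: bool
    gaze_on_path: bool
    hazard_gazed: bool


def build_walking_path(
    frame_width: float, frame_height: float, config: PathConfig = PathConfig()
) -> WalkingPath:
    """Construct the immediate-walking-path trapezoid for a frame size.

    The base is centred horizontally, ``round(base_width_fraction * W)``
    pixels wide, on the bottom row; the top edge sits at
    ``round(top_y_fraction * H)`` from the top of the frame.
    """
    if frame_width <= 0 or frame_height <= 0:
        raise ValueError("frame dimensions must be positive")
    cx = frame_width / 2.0
    base_w = round(config.base_width_fraction * frame_width)
    top_w = round(config.top_width_fraction * frame_width)
    top_y = round(config.top_y_fraction * frame_height)
    return WalkingPath(
        bottom_left=(cx - base_w / 2.0, float(frame_height)),
        bottom_right=(cx + base_w / 2.0, float(frame_height)),
        top_right=(cx + top_w / 2.0, float(top_y)),
        top_left=(cx - top_w / 2.0, float(top_y)),
    )


def _cell_range(lo: float, hi: float, scale: float, n: int) -> tuple[int, int]:
    """Indices [a, b) of cells whose footprint intersects [lo, hi).

    Outward rounding: floor on the lower edge, ceil on the upper, then
    clipped to the grid.  Cells that merely touch the interval boundary
    at a point are excluded (the intersection must have positive length).
    """
    a = int(math.floor(lo / scale))
    b = int(math.ceil(hi / scale))
    return max(a, 0), min(b, n)


Shape = Union[BoundingBox, Circle, WalkingPath]


def rasterize(
    shape: Shape,
    frame_width: float,
    frame_height: float,
    mask_resolution: tuple[int, int] = DEFAULT_MASK_RESOLUTION,
) -> BinaryMask:
    """Rasterize a shape into a reduced-resolution binary mask.

    A cell is set iff its full-frame pixel footprint intersects the shape
    (after clipping the shape to the frame).  A shape entirely outside
    the frame yields an all-zero mask.
    """
    w_m, h_m = mask_resolution
    if w_m <= 0 or h_m <= 0:
        raise ValueError("mask resolution must be positive")
    grid = np.zeros((h_m, w_m), dtype=np.uint8)
    sx = frame_width / w_m
    sy = frame_height / h_m

    if isinstance(shape, BoundingBox):
        clipped = shape.clip(frame_width, frame_height)
        if clipped is not None:
            c0, c1 = _cell_range(clipped.x_min, clipped.x_max, sx, w_m)
            r0, r1 = _cell_range(clipped.y_min, clipped.y_max, sy, h_m)
            grid[r0:r1, c0:c1] = 1
    elif isinstance(shape, Circle):
        cx, cy = shape.center
        r = shape.radius
        r0, r1 = _cell_range(max(cy - r, 0.0), min(cy + r, frame_height), sy, h_m)
        c0, c1 = _cell_range(max(cx - r, 0.0), min(cx + r, frame_width), sx, w_m)
        if r0 < r1 and c0 < c1:
            cols = np.arange(c0, c1)
            rows = np.arange(r0, r1)
            # distance from the circle centre to each cell's footprint
            # rectangle; zero when the centre lies inside the footprint
            dx = np.maximum.reduce(
                [cols * sx - cx, cx - (cols + 1) * sx, np.zeros_like(cols, dtype=float)]
            )
            dy = np.maximum.reduce(
                [rows * sy - cy, cy - (rows + 1) * sy, np.zeros_like(rows, dtype=float)]
            )
            inside = (dx[None, :] ** 2 + dy[:, None] ** 2) < r * r
            grid[r0:r1, c0:c1] = inside.astype(np.uint8)
    elif isinstance(shape, WalkingPath):
        top = max(shape.top_y, 0.0)
        bottom = min(shape.bottom_y, frame_height)
        if bottom > top:
            r0, r1 = _cell_range(top, bottom, sy, h_m)
            for row in range(r0, r1):
                y_lo = max(row * sy, top)
                y_hi = min((row + 1) * sy, bottom)
                # the trapezoid's x-extent over [y_lo, y_hi] is the union
                # of the extents at the two ends (edges are linear in y)
                e_lo = shape.x_extent_at(y_lo)
                e_hi = shape.x_extent_at(y_hi)
                extents = [e for e in (e_lo, e_hi) if e is not None]
                if not extents:
                    continue
                left = max(min(e[0] for e in extents), 0.0)
                right = min(max(e[1] for e in extents), frame_width)
                if right > left:
                    c0, c1 = _cell_range(left, right, sx, w_m)
                    grid[row, c0:c1] = 1
    else:
        raise TypeError(f"cannot rasterize {type(shape).__name__}")

    return BinaryMask(grid, frame_width, frame_height)


def detect_overlaps(
    frame: FrameRecord,
    path: WalkingPath,
    mask_resolution: tuple[int, int] = DEFAULT_MASK_RESOLUTION,
    gaze_radius: float = DEFAULT_GAZE_RADIUS,
) -> list[OverlapVerdict]:
    """Per-detection in-path / gazed verdicts for one frame.

    Each detection's box is clipped to the frame and rasterized; the
    verdicts are the AND-overlaps with the path mask and with the gaze
    mask (a filled circle around the gaze point).  Missing or invalid
    gaze yields ``gazed=False`` for every object.
    """
    path_mask = rasterize(path, frame.width, frame.height, mask_resolution)
    gaze_mask = _gaze_mask(frame, mask_resolution, gaze_radius)
    verdicts = []
    for det in frame.detections:
        obj_mask = rasterize(det.box, frame.width, frame.height, mask_resolution)
        in_path = obj_mask.overlaps(path_mask)
        gazed = gaze_mask is not None and obj_mask.overlaps(gaze_mask)
        verdicts.append(OverlapVerdict(det, in_path=in_path, gazed=gazed))
    return verdicts


def _gaze_mask(
    frame: FrameRecord,
    mask_resolution: tuple[int, int],
    gaze_radius: float,
) -> Optional[BinaryMask]:
    g = frame.gaze
    if g is None or not g.valid:
        return None
    circle = Circle(center=(g.x, g.y), radius=gaze_radius)
    mask = rasterize(circle, frame.width, frame.height, mask_resolution)
    if not mask.grid.any():
        return None
    return mask


def gaze_in_path(
    frame: FrameRecord,
    path: WalkingPath,
    mask_resolution: tuple[int, int] = DEFAULT_MASK_RESOLUTION,
    gaze_radius: float = DEFAULT_GAZE_RADIUS,
) -> bool:
    """Whether the wearer's gaze circle overlaps the walking path."""
    gaze_mask = _gaze_mask(frame, mask_resolution, gaze_radius)
    if gaze_mask is None:
        return False
    path_mask = rasterize(path, frame.width, frame.height, mask_resolution)
    return gaze_mask.overlaps(path_mask)


def summarize_frame(
    verdicts: Sequence[OverlapVerdict],
    taxonomy: Taxonomy,
    *,
    frame_index: int = 0,
    timestamp: float = 0.0,
    gaze_on_path: bool = False,
) -> FrameContext:
    """Collapse per-object verdicts into a frame-level hazard summary.

    ``hazard_in_path`` is the OR, over detections whose class carries the
    fall-risk role, of their in-path flags; context-only classes (e.g. a
    bed) never raise it.  ``hazard_gazed`` marks frames where at least
    one in-path hazard was also gazed.
    """
    hazard_in_path = False
    hazard_gazed = False
    for v in verdicts:
        if is_hazard_class(taxonomy, v.detection.class_name):
            if v.in_path:
                hazard_in_path = True
                if v.gazed:
                    hazard_gazed = True
    return FrameContext(
        frame_index=frame_index,
        timestamp=timestamp,
        verdicts=list(verdicts),
        hazard_in_path=hazard_in_path,
        gaze_on_path=gaze_on_path,
        hazard_gazed=hazard_gazed,
    )


def analyze_frame(
    frame: FrameRecord,
    path: WalkingPath,
    taxonomy: Taxonomy,
    mask_resolution: tuple[int, int] = DEFAULT_MASK_RESOLUTION,
    gaze_radius: float = DEFAULT_GAZE_RADIUS,
) -> FrameContext:
    """Convenience wrapper: verdicts + frame summary in one call."""
    verdicts = detect_overlaps(frame, path, mask_resolution, gaze_radius)
    on_path = gaze_in_path(frame, path, mask_resolution, gaze_radius)
    return summarize_frame(
        verdicts,
        taxonomy,
        frame_index=frame.index,
        timestamp=frame.timestamp,
        gaze_on_path=on_path,
    )


def attention_on_hazards(
    contexts: Sequence[FrameContext], window: float
) -> list[tuple[float, Optional[float]]]:
    """Per-window fraction of hazard-present frames whose hazard was gazed.

    Frames are grouped into consecutive windows of ``window`` seconds
    starting at the first frame's timestamp.  Each entry is
    ``(window_start_time, fraction)``; the fraction is ``None`` for
    windows containing no hazard-present frames (attention on hazards is
    undefined when there is no hazard to attend to).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not contexts:
        return []
    ts = [c.timestamp for c in contexts]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError("frame contexts must be time-ordered")
    t0 = ts[0]
    n_windows = int(math.floor((ts[-1] - t0) / window)) + 1
    hazard_frames = [0] * n_windows
    gazed_frames = [0] * n_windows
    for c in contexts:
        k = min(int((c.timestamp - t0) / window), n_windows - 1)
        if c.hazard_in_path:
            hazard_frames[k] += 1
            if c.hazard_gazed:
                gazed_frames[k] += 1
    out: list[tuple[float, Optional[float]]] = []
    for k in range(n_windows):
        start = t0 + k * window
        frac = gazed_frames[k] / hazard_frames[k] if hazard_frames[k] else None
        out.append((start, frac))
    return out


def contexts_to_rows(contexts: Iterable[FrameContext]) -> list[dict]:
    """Flatten contexts into one dict per (frame, detection) for CSV export."""
    rows = []
    for c in contexts:
        for v in c.verdicts:
            b = v.detection.box
            rows.append(
                {
                    "frame_index": c.frame_index,
                    "timestamp": c.timestamp,
                    "class": v.detection.class_name,
                    "x_min": b.x_min,
                    "y_min": b.y_min,
                    "x_max": b.x_max,
                    "y_max": b.y_max,
                    "confidence": v.detection.confidence,
                    "in_path": v.in_path,
                    "gazed": v.gazed,
                }
            )
    return rows


def frame_summary_rows(contexts: Iterable[FrameContext]) -> list[dict]:
    return [
        {
            "frame_index": c.frame_index,
            "timestamp": c.timestamp,
            "n_detections": len(c.verdicts),
            "hazard_in_path": c.hazard_in_path,
            "gaze_on_path": c.gaze_on_path,
            "hazard_gazed": c.hazard_gazed,
        }
        for c in contexts
    ]
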