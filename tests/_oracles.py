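"""Independent brute-force oracles used by the tests.

Everything here recomputes geometry from first principles (pixel unit
squares, direct enumeration) without calling the mask engine under test.
A pixel (ix, iy) covers the unit square [ix, ix+1) x [iy, iy+1); a pixel
belongs to a shape when that square and the shape intersect with positive
area, mirroring the package's outward-rounding contract at the native
resolution.
"""

from __future__ import annotations

import numpy as np


def pixel_path_mask(width: int, height: int, base_frac=0.50, top_frac=0.15, top_y_frac=0.55) -> np.ndarray:
    """Full-resolution boolean mask of the walking-path trapezoid.

    Built row by row from the trapezoid's defining fractions with local
    interpolation arithmetic only.
    """
    cx = width / 2.0
    base_w = round(base_frac * width)
    top_w = round(top_frac * width)
    top_y = round(top_y_frac * height)
    bottom_y = float(height)
    mask = np.zeros((height, width), dtype=bool)

    def extent(y: float) -> tuple[float, float]:
        t = 1.0 if bottom_y == top_y else (y - top_y) / (bottom_y - top_y)
        half = (top_w + t * (base_w - top_w)) / 2.0
        return cx - half, cx + half

    for iy in range(height):
        y_lo = max(float(iy), float(top_y))
        y_hi = min(float(iy + 1), bottom_y)
        if y_hi <= y_lo:
            continue
        # extent union over the row's slice of the trapezoid (linear edges)
        l0, r0 = extent(y_lo)
        l1, r1 = extent(y_hi)
        left, right = min(l0, l1), max(r0, r1)
        a = int(np.floor(max(left, 0.0)))
        b = int(np.ceil(min(right, width)))
        if b > a:
            mask[iy, a:b] = True
    return mask


def pixel_box_mask(x0: float, y0: float, x1: float, y1: float, width: int, height: int) -> np.ndarray:
    """Pixels whose unit square intersects the (clipped) box."""
    mask = np.zeros((height, width), dtype=bool)
    a, b = int(np.floor(max(x0, 0))), int(np.ceil(min(x1, width)))
    c, d = int(np.floor(max(y0, 0))), int(np.ceil(min(y1, height)))
    if b > a and d > c:
        mask[c:d, a:b] = True
    return mask


def pixel_disc_mask(cx: float, cy: float, r: float, width: int, height: int) -> np.ndarray:
    """Pixels whose unit square intersects the open disc (clamp distance)."""
    xs = np.arange(width)
    ys = np.arange(height)
    dx = np.maximum.reduce([xs - cx, cx - (xs + 1), np.zeros(width)])
    dy = np.maximum.reduce([ys - cy, cy - (ys + 1), np.zeros(height)])
    return (dx[None, :] ** 2 + dy[:, None] ** 2) < r * r


def cell_span(pixel_mask: np.ndarray, frame_width: int, frame_height: int, mask_resolution=(200, 200)) -> tuple[int, int]:
    """How many downscaled-grid rows and columns the pixel region touches."""
    if not pixel_mask.any():
        return (0, 0)
    rows, cols = np.nonzero(pixel_mask)
    sy = frame_height / mask_resolution[1]
    sx = frame_width / mask_resolution[0]
    cell_rows = np.unique((rows / sy).astype(int))
    cell_cols = np.unique((cols / sx).astype(int))
    return (len(cell_rows), len(cell_cols))


def iou_by_pixel_count(ax0, ay0, ax1, ay1, bx0, by0, bx1, by1) -> float:
    """IoU by counting integer pixels in intersection and union."""
    w = int(max(ax1, bx1)) + 1
    h = int(max(ay1, by1)) + 1
    a = pixel_box_mask(ax0, ay0, ax1, ay1, w, h)
    b = pixel_box_mask(bx0, by0, bx1, by1, w, h)
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0
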