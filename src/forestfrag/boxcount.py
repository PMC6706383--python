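"""Box-counting dimension and the Fractal Fragmentation Index (FFI).

The box-counting dimension of a binary set is the slope of log N(eps)
against log(1/eps), where N(eps) is the number of cells of a fixed,
non-overlapping grid of side eps that contain at least one foreground
pixel.  FFI is the dimension of the area set minus the dimension of its
(inner-boundary) perimeter set: values near 1 indicate one compact
object, values near 0 indicate small, fragmented objects, and a
single-pixel mask — whose perimeter set equals its area set — gives
exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import BinaryRaster

__all__ = [
    "BoxCountResult",
    "FFIResult",
    "default_boxcount_scales",
    "extract_perimeter",
    "box_count",
    "compute_ffi",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class BoxCountResult:
    scales: list[int]
    counts: list[int]
    slope: float
    intercept: float
    r_squared: float


@dataclass
class FFIResult:
    d_area: float
    d_perimeter: float
    ffi: float
    area_fit: BoxCountResult | None = None
    perimeter_fit: BoxCountResult | None = None


def default_boxcount_scales(shape: tuple[int, int]) -> list[int]:
    """Dyadic box sides from 2 up to min(H, W)/4.

    eps = 1 is excluded by default: N(1) is just the pixel count and
    tends to dominate the area-set fit.  The coarse end is capped at a
    quarter of the short image side: beyond that a handful of boxes
    covers any set and the perimeter-set slope collapses towards the
    trivial log N floor, visibly biasing FFI.
    """
    top = min(shape) // 4
    scales = []
    eps = 2
    while eps <= top:
        scales.append(eps)
        eps *= 2
    return scales


def extract_perimeter(mask: BinaryRaster) -> BinaryRaster:
    """Inner morphological boundary under 4-adjacency.

    A pixel belongs to the perimeter iff it is foreground and at least
    one 4-neighbour is background or lies outside the image.  With this
    definition a single pixel (or any 1-pixel-wide object) is its own
    perimeter, which makes the single-pixel FFI identity exact.
    """
    fg = mask.bool()
    interior = ndimage.binary_erosion(fg, structure=_CROSS, border_value=0)
    return BinaryRaster(mask=(fg & ~interior).astype(np.uint8), pixel_size_m=mask.pixel_size_m)


def _occupied_boxes(fg: np.ndarray, eps: int) -> int:
    h, w = fg.shape
    nh = -(-h // eps)
    nw = -(-w // eps)
    if nh * eps != h or nw * eps != w:
        padded = np.zeros((nh * eps, nw * eps), dtype=bool)
        padded[:h, :w] = fg
        fg = padded
    blocks = fg.reshape(nh, eps, nw, eps)
    return int(blocks.any(axis=(1, 3)).sum())


def _loglog_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def box_count(mask: BinaryRaster, scales: list[int] | None = None) -> BoxCountResult:
    """Occupied-box counts on a top-left-anchored fixed grid, and the
    OLS dimension estimate from the log-log plot.

    Partial boxes at the right/bottom edges are included.  No grid-offset
    averaging is performed: identical input and scales give identical
    counts.
    """
    fg = mask.bool()
    if not fg.any():
        raise ValueError("box_count: no foreground pixels")
    if scales is None:
        scales = default_boxcount_scales(fg.shape)
    scales = sorted(int(e) for e in scales)
    if len(scales) < 3:
        raise ValueError(f"need at least 3 scales for a dimension fit, got {len(scales)}")
    lo, hi = scales[0], scales[-1]
    if lo < 1 or hi > min(fg.shape):
        raise ValueError(
            f"scales must lie in [1, {min(fg.shape)}], got [{lo}, {hi}]"
        )
    counts = [_occupied_boxes(fg, eps) for eps in scales]
    x = np.log(1.0 / np.asarray(scales, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    slope, intercept, r2 = _loglog_fit(x, y)
    return BoxCountResult(scales=list(scales), counts=counts, slope=slope,
                          intercept=intercept, r_squared=r2)


def compute_ffi(mask: BinaryRaster, scales: list[int] | None = None) -> FFIResult:
    """FFI = D(area set) - D(perimeter set), both box-counted on the
    same grid and scale set."""
    fg = mask.bool()
    if not fg.any():
        raise ValueError("compute_ffi: no foreground pixels")
    if scales is None:
        scales = default_boxcount_scales(fg.shape)
    area_fit = box_count(mask, scales)
    perim_fit = box_count(extract_perimeter(mask), scales)
    return FFIResult(
        d_area=area_fit.slope,
        d_perimeter=perim_fit.slope,
        ffi=area_fit.slope - perim_fit.slope,
        area_fit=area_fit,
        perimeter_fit=perim_fit,
    )
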