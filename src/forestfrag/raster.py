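"""Raster containers and single-band TIFF/GeoTIFF input/output.

Every analysis module in the package consumes one of two containers:
:class:`GrayscaleRaster` (small-integer grids such as canopy percent or
loss-year codes) and :class:`BinaryRaster` ({0,1} masks).  Grids are
row-major, 0-based, with row 0 at the top; the pixel is assumed square
with its side length in metres carried on the container (Landsat-derived
forest-change layers are ~30 m).

Inputs must already be in a metric projection: this package never
reprojects, it only consumes ``pixel_size_m``.  The pixel size is encoded
in GeoTIFF files through the ModelPixelScale tag and recovered on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import tifffile

__all__ = [
    "GrayscaleRaster",
    "BinaryRaster",
    "ForestLayerSet",
    "RasterFormatError",
    "read_raster",
    "write_raster",
    "binarize",
    "DEFAULT_PIXEL_SIZE_M",
]

DEFAULT_PIXEL_SIZE_M = 30.0

#: GeoTIFF ModelPixelScaleTag — (sx, sy, sz) pixel size in CRS units.
_MODEL_PIXEL_SCALE = 33550
#: GDAL nodata tag (ASCII).
_GDAL_NODATA = 42113


class RasterFormatError(ValueError):
    """Raised for rasters that violate the single-band integer contract."""


def _validate_grid(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 2 or values.size == 0:
        raise RasterFormatError(
            f"raster grid must be 2D and non-empty, got shape {values.shape}"
        )
    return values


@dataclass
class GrayscaleRaster:
    """Single-band integer raster with a square metric pixel."""

    values: np.ndarray
    pixel_size_m: float = DEFAULT_PIXEL_SIZE_M
    nodata: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = _validate_grid(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise RasterFormatError(
                f"grayscale raster requires an integer dtype, got {self.values.dtype}"
            )
        if not self.pixel_size_m > 0:
            raise ValueError(f"pixel_size_m must be positive, got {self.pixel_size_m}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BinaryRaster:
    """{0,1} mask with a square metric pixel; the universal metric input."""

    mask: np.ndarray
    pixel_size_m: float = DEFAULT_PIXEL_SIZE_M

    def __post_init__(self) -> None:
        mask = _validate_grid(self.mask)
        if mask.dtype == bool:
            mask = mask.astype(np.uint8)
        if not np.issubdtype(mask.dtype, np.integer):
            raise RasterFormatError(
                f"binary raster requires an integer dtype, got {mask.dtype}"
            )
        bad = (mask != 0) & (mask != 1)
        if bad.any():
            raise RasterFormatError(
                f"binary raster contains {int(bad.sum())} values outside {{0,1}}"
            )
        self.mask = mask.astype(np.uint8, copy=False)
        if not self.pixel_size_m > 0:
            raise ValueError(f"pixel_size_m must be positive, got {self.pixel_size_m}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def bool(self) -> np.ndarray:
        return self.mask.astype(bool)


@dataclass
class ForestLayerSet:
    """The three-layer forest-change stack.

    ``cover_baseline``
        canopy mask for the baseline year (before any recorded loss),
    ``loss_year``
        integer codes: 0 = never lost, t = lost in year ``years[t-1]``,
    ``gain_cumulative``
        cumulative regeneration over the whole period (a single layer;
        per-year gain is not part of the data model).
    """

    cover_baseline: BinaryRaster
    loss_year: GrayscaleRaster
    gain_cumulative: BinaryRaster
    years: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {
            self.cover_baseline.shape,
            self.loss_year.shape,
            self.gain_cumulative.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"layer shapes differ: {sorted(shapes)}")
        sizes = {
            self.cover_baseline.pixel_size_m,
            self.loss_year.pixel_size_m,
            self.gain_cumulative.pixel_size_m,
        }
        if len(sizes) != 1:
            raise ValueError(f"layer pixel sizes differ: {sorted(sizes)}")
        self.years = list(self.years)
        t_max = int(self.loss_year.values.max(initial=0))
        if t_max > len(self.years):
            raise ValueError(
                f"loss-year code {t_max} exceeds the {len(self.years)} labelled years"
            )

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def pixel_size_m(self) -> float:
        return self.cover_baseline.pixel_size_m


def read_raster(path: os.PathLike | str, pixel_size_m: Optional[float] = None) -> GrayscaleRaster:
    """Read a single-band TIFF/GeoTIFF into a :class:`GrayscaleRaster`.

    Pixel size comes from the GeoTIFF ModelPixelScale tag when present,
    else from ``pixel_size_m``, else the 30 m default.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            spp = page.tags.valueof("SamplesPerPixel", 1)
            if values.ndim != 2 or (spp is not None and spp > 1):
                bands = spp if spp and spp > 1 else (values.shape[-1] if values.ndim > 2 else 1)
                raise RasterFormatError(
                    f"expected a single-band raster, got {bands} bands in {path}"
                )
            scale = page.tags.valueof(_MODEL_PIXEL_SCALE)
            nodata_tag = page.tags.valueof(_GDAL_NODATA)
    except (FileNotFoundError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read raster {path}: {exc}") from exc

    if scale is not None and len(scale) >= 1 and scale[0] > 0:
        px = float(scale[0])
    elif pixel_size_m is not None:
        px = float(pixel_size_m)
    else:
        px = DEFAULT_PIXEL_SIZE_M
    nodata = None
    if nodata_tag is not None:
        try:
            nodata = int(float(str(nodata_tag).strip("\x00 ")))
        except ValueError:
            nodata = None
    return GrayscaleRaster(values=values, pixel_size_m=px, nodata=nodata)


def write_raster(raster: GrayscaleRaster | BinaryRaster, path: os.PathLike | str) -> None:
    """Write a raster as a single-band GeoTIFF (bit-exact round trip)."""
    if isinstance(raster, BinaryRaster):
        values = raster.mask
        nodata = None
    else:
        values = raster.values
        nodata = raster.nodata
    px = raster.pixel_size_m
    extratags = [(_MODEL_PIXEL_SCALE, "d", 3, (px, px, 0.0), True)]
    if nodata is not None:
        text = f"{nodata}\x00"
        extratags.append((_GDAL_NODATA, "s", len(text), text, True))
    try:
        tifffile.imwrite(path, values, extratags=extratags)
    except (OSError, PermissionError) as exc:
        raise IOError(f"cannot write raster {path}: {exc}") from exc


def binarize(
    raster: GrayscaleRaster,
    threshold: int = 0,
    mode: str = ">0",
) -> BinaryRaster:
    """Threshold a grayscale raster to a {0,1} mask.

    ``mode=">0"`` keeps strictly positive pixels (the default for layers
    that are already near-binary); ``mode=">=t"`` keeps pixels at or above
    ``threshold`` (the conventional canopy-percent cut for Hansen-style
    tree-cover layers).  Nodata pixels always map to 0.
    """
    values = raster.values
    if mode == ">0":
        mask = values > 0
    elif mode == ">=t":
        lo, hi = int(values.min()), int(values.max())
        if not (lo <= threshold <= hi) and lo != hi:
            raise ValueError(
                f"threshold {threshold} outside value range [{lo}, {hi}]"
            )
        mask = values >= threshold
    else:
        raise ValueError(f"unknown binarize mode {mode!r} (use '>0' or '>=t')")
    if raster.nodata is not None:
        mask = mask & (values != raster.nodata)
    return BinaryRaster(mask=mask.astype(np.uint8), pixel_size_m=raster.pixel_size_m)
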