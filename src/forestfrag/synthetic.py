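"""Synthetic forest-change scenarios with recorded ground truth.

The generator emulates the three-layer structure of satellite-derived
global forest-change products: a baseline canopy mask, a loss-year layer
(integer code t = lost in year t, 0 = never lost) and a single
cumulative regeneration layer.  Each year places a configurable number
of loss patches inside remaining cover.  A patch either extends the
existing loss front (its seed pixel is drawn 8-adjacent to previously
accumulated loss, probability ``clustering_prob``) or opens a fresh
location (seed and growth kept non-adjacent to all prior loss), which
mirrors the compact-vs-scattered logging regimes the metrics are meant
to separate.  Patch pixel counts are drawn from a lognormal; patches are
grown as connected blobs by randomised dilation from the seed, and
same-year patches are kept mutually non-adjacent so that per-year
particle statistics match the recorded truth exactly.

``make_primitive`` provides the deterministic analytic fixtures (line,
filled rectangle, frame, checkerboard, scattered squares) on which the
fractal estimators have closed-form values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .raster import BinaryRaster, ForestLayerSet, GrayscaleRaster, read_raster, write_raster

__all__ = [
    "ScenarioConfig",
    "YearTruth",
    "ScenarioTruth",
    "make_primitive",
    "generate_scenario",
    "write_scenario",
    "read_scenario",
]

_S8 = np.ones((3, 3), dtype=bool)


@dataclass
class ScenarioConfig:
    """Knobs of the scenario generator.

    ``patch_size_distribution`` is (log-mean, log-sd) of the lognormal
    patch pixel count; the defaults put the mean loss patch near 15
    pixels = 1.3 ha at 30 m, between the quiet (<1 ha) and intense
    (>1.5 ha) logging regimes.  ``clustering_prob`` is the probability
    that a new patch seeds adjacent to existing loss rather than at a
    fresh location; ``gain_fraction`` is the share of cumulative loss
    regenerated by the end of the period (0.466 by default, matching a
    landscape where under half the felled area regrows).
    """

    shape: tuple[int, int] = (128, 128)
    pixel_size_m: float = 30.0
    n_years: int = 14
    cover_fraction: float = 0.68
    patches_per_year: int = 12
    patch_size_distribution: tuple[float, float] = (2.5, 0.6)
    clustering_prob: float = 0.5
    gain_fraction: float = 0.466
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cover_fraction <= 1:
            raise ValueError(f"cover_fraction must be in (0, 1], got {self.cover_fraction}")
        for name in ("clustering_prob", "gain_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_years < 1:
            raise ValueError(f"n_years must be >= 1, got {self.n_years}")
        if self.patches_per_year < 1:
            raise ValueError(f"patches_per_year must be >= 1, got {self.patches_per_year}")


@dataclass
class YearTruth:
    year_index: int                  # 1-based loss code
    patch_areas_px: list[int]        # actual pixel count of each placed patch
    n_fresh: int                     # patches not 8-adjacent to prior loss

    @property
    def n_patches(self) -> int:
        return len(self.patch_areas_px)


@dataclass
class ScenarioTruth:
    per_year: list[YearTruth]
    cover_pixels: int
    gain_pixels: int

    def total_loss_pixels(self) -> int:
        return sum(sum(y.patch_areas_px) for y in self.per_year)


# ---------------------------------------------------------------------------
# analytic primitives

def make_primitive(kind: str, shape: tuple[int, int], **params) -> BinaryRaster:
    """Deterministic fixture geometries for the analytic anchors."""
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError(f"invalid shape {shape}")
    grid = np.zeros(shape, dtype=np.uint8)
    px = params.pop("pixel_size_m", 30.0)

    if kind == "single_pixel":
        r = params.pop("row", h // 2)
        c = params.pop("col", w // 2)
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"pixel ({r}, {c}) outside shape {shape}")
        grid[r, c] = 1
    elif kind == "h_line":
        r = params.pop("row", h // 2)
        if not 0 <= r < h:
            raise ValueError(f"row {r} outside shape {shape}")
        grid[r, :] = 1
    elif kind == "filled_rect":
        top = params.pop("top", 0)
        left = params.pop("left", 0)
        hh = params.pop("height", h - top)
        ww = params.pop("width", w - left)
        if top < 0 or left < 0 or top + hh > h or left + ww > w or hh < 1 or ww < 1:
            raise ValueError(f"rect {(top, left, hh, ww)} exceeds shape {shape}")
        grid[top : top + hh, left : left + ww] = 1
    elif kind == "frame":
        top = params.pop("top", 0)
        left = params.pop("left", 0)
        hh = params.pop("height", h - top)
        ww = params.pop("width", w - left)
        if top < 0 or left < 0 or top + hh > h or left + ww > w or hh < 2 or ww < 2:
            raise ValueError(f"frame {(top, left, hh, ww)} exceeds shape {shape}")
        grid[top : top + hh, left : left + ww] = 1
        grid[top + 1 : top + hh - 1, left + 1 : left + ww - 1] = 0
    elif kind == "checkerboard":
        cell = params.pop("cell", 1)
        if cell < 1:
            raise ValueError(f"cell must be >= 1, got {cell}")
        rr, cc = np.indices(shape)
        grid[:] = (((rr // cell) + (cc // cell)) % 2 == 0).astype(np.uint8)
    elif kind == "scattered_squares":
        k = params.pop("k", 9)
        side = params.pop("side", 4)
        gap = params.pop("gap", 8)
        step = side + gap
        per_row = max(1, (w - side) // step + 1)
        placed = 0
        for i in range(k):
            r = (i // per_row) * step
            c = (i % per_row) * step
            if r + side > h or c + side > w:
                raise ValueError(
                    f"{k} squares of side {side} with gap {gap} do not fit in {shape}"
                )
            grid[r : r + side, c : c + side] = 1
            placed += 1
        assert placed == k
    else:
        raise ValueError(f"unknown primitive kind {kind!r}")
    return BinaryRaster(mask=grid, pixel_size_m=px)


# ---------------------------------------------------------------------------
# scenario generation

def _grow_blob(
    rng: np.random.Generator,
    seed_pixel: tuple[int, int],
    allowed: np.ndarray,
    target: int,
) -> list[tuple[int, int]]:
    """Randomised dilation from the seed inside ``allowed``; returns a
    connected pixel set of at most ``target`` pixels."""
    h, w = allowed.shape
    blob = {seed_pixel}
    frontier = [seed_pixel]
    while len(blob) < target:
        candidates: list[tuple[int, int]] = []
        for (r, c) in frontier:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and allowed[rr, cc] and (rr, cc) not in blob:
                        candidates.append((rr, cc))
        if not candidates:
            break
        pick = candidates[rng.integers(len(candidates))]
        blob.add(pick)
        frontier = list(blob)
    return sorted(blob)


def generate_scenario(config: ScenarioConfig) -> tuple[ForestLayerSet, ScenarioTruth]:
    """Generate a three-layer stack plus ground truth, reproducibly from
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    h, w = config.shape

    # Baseline cover: smoothed Gaussian noise thresholded at the quantile
    # that realises cover_fraction (within one pixel).
    noise = rng.normal(size=(h, w))
    smooth = ndimage.gaussian_filter(noise, sigma=3.0)
    thr = np.quantile(smooth, 1.0 - config.cover_fraction)
    cover = smooth > thr

    loss_year = np.zeros((h, w), dtype=np.uint8)
    log_mu, log_sd = config.patch_size_distribution
    per_year: list[YearTruth] = []

    for t in range(1, config.n_years + 1):
        prev_loss = loss_year > 0
        near_prev = ndimage.binary_dilation(prev_loss, structure=_S8)
        year_mask = np.zeros((h, w), dtype=bool)
        areas: list[int] = []
        n_fresh = 0
        for _ in range(config.patches_per_year):
            near_year = ndimage.binary_dilation(year_mask, structure=_S8)
            open_cover = cover & ~prev_loss & ~near_year
            if not open_cover.any():
                raise RuntimeError(
                    f"cover exhausted in year {t}: no room left for loss patches"
                )
            want_cluster = prev_loss.any() and rng.random() < config.clustering_prob
            cluster_sites = open_cover & near_prev
            fresh_sites = open_cover & ~near_prev
            if want_cluster and cluster_sites.any():
                sites, fresh = cluster_sites, False
            elif fresh_sites.any():
                sites, fresh = fresh_sites, True
            elif cluster_sites.any():
                sites, fresh = cluster_sites, False
            else:  # pragma: no cover - open_cover non-empty implies one branch
                raise RuntimeError(f"cover exhausted in year {t}")
            rows, cols = np.nonzero(sites)
            i = int(rng.integers(rows.size))
            seed_pixel = (int(rows[i]), int(cols[i]))
            target = max(1, int(round(rng.lognormal(log_mu, log_sd))))
            allowed = open_cover & ~near_prev if fresh else open_cover
            blob = _grow_blob(rng, seed_pixel, allowed, target)
            for (r, c) in blob:
                loss_year[r, c] = t
                year_mask[r, c] = True
            areas.append(len(blob))
            n_fresh += int(fresh)
        per_year.append(YearTruth(year_index=t, patch_areas_px=areas, n_fresh=n_fresh))

    cum_loss = loss_year > 0
    n_loss = int(cum_loss.sum())
    n_gain = int(round(config.gain_fraction * n_loss))
    gain = np.zeros((h, w), dtype=np.uint8)
    if n_gain > 0:
        rows, cols = np.nonzero(cum_loss)
        pick = rng.choice(rows.size, size=n_gain, replace=False)
        gain[rows[pick], cols[pick]] = 1

    layers = ForestLayerSet(
        cover_baseline=BinaryRaster(cover.astype(np.uint8), config.pixel_size_m),
        loss_year=GrayscaleRaster(loss_year, config.pixel_size_m),
        gain_cumulative=BinaryRaster(gain, config.pixel_size_m),
        years=list(range(1, config.n_years + 1)),
    )
    truth = ScenarioTruth(
        per_year=per_year,
        cover_pixels=int(cover.sum()),
        gain_pixels=n_gain,
    )
    return layers, truth


# ---------------------------------------------------------------------------
# on-disk layout mirroring the real three-layer stacks

_LAYER_FILES = {
    "cover": "tree_cover.tif",
    "loss": "loss_year.tif",
    "gain": "gain_cumulative.tif",
}


def write_scenario(
    outdir: Path | str,
    layers: ForestLayerSet,
    truth: Optional[ScenarioTruth] = None,
) -> None:
    """Write a scenario as a directory of GeoTIFFs plus a truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_raster(layers.cover_baseline, outdir / _LAYER_FILES["cover"])
    write_raster(layers.loss_year, outdir / _LAYER_FILES["loss"])
    write_raster(layers.gain_cumulative, outdir / _LAYER_FILES["gain"])
    (outdir / "years.txt").write_text("\n".join(str(y) for y in layers.years) + "\n")
    if truth is not None:
        lines = ["year_index,n_patches,n_fresh,patch_areas_px"]
        for y in truth.per_year:
            areas = ";".join(str(a) for a in y.patch_areas_px)
            lines.append(f"{y.year_index},{y.n_patches},{y.n_fresh},{areas}")
        (outdir / "truth.csv").write_text("\n".join(lines) + "\n")


def read_scenario(indir: Path | str) -> ForestLayerSet:
    """Read a scenario directory back into a :class:`ForestLayerSet`."""
    indir = Path(indir)
    cover = read_raster(indir / _LAYER_FILES["cover"])
    loss = read_raster(indir / _LAYER_FILES["loss"])
    gain = read_raster(indir / _LAYER_FILES["gain"])
    years_file = indir / "years.txt"
    if years_file.exists():
        years = [int(s) for s in years_file.read_text().split()]
    else:
        years = list(range(1, int(loss.values.max(initial=0)) + 1))
    return ForestLayerSet(
        cover_baseline=BinaryRaster(cover.values, cover.pixel_size_m),
        loss_year=loss,
        gain_cumulative=BinaryRaster(gain.values, gain.pixel_size_m),
        years=years,
    )
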