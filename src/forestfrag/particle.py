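"""Particle (patch) analysis: connected-component statistics of a mask.

A "particle" is a forest patch — a maximal set of foreground pixels
connected under 4- or 8-adjacency.  The summaries here (patch count,
total area in hectares, average patch size) are the standard landscape
descriptors reported per layer and year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import BinaryRaster

__all__ = [
    "LabeledRaster",
    "ParticleSummary",
    "label_components",
    "summarize_particles",
    "count_new_patches",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int),
    8: np.ones((3, 3), dtype=int),
}


def _structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}") from None


@dataclass
class LabeledRaster:
    """Component labels: 0 = background, 1..K = patch ids."""

    labels: np.ndarray
    connectivity: int = 8

    @property
    def n_patches(self) -> int:
        return int(self.labels.max(initial=0))


@dataclass
class ParticleSummary:
    count: int
    total_area_ha: float
    average_size_ha: float
    sizes_ha: list[float] = field(default_factory=list)


def label_components(mask: BinaryRaster, connectivity: int = 8) -> LabeledRaster:
    """Label connected patches of a binary mask."""
    labels, _ = ndimage.label(mask.mask, structure=_structure(connectivity))
    return LabeledRaster(labels=labels, connectivity=connectivity)


def summarize_particles(labeled: LabeledRaster, pixel_size_m: float) -> ParticleSummary:
    """Patch count and per-patch areas in hectares.

    Per-patch area = pixel count x pixel_size_m^2 / 10,000.
    """
    k = labeled.n_patches
    if k == 0:
        return ParticleSummary(count=0, total_area_ha=0.0, average_size_ha=0.0, sizes_ha=[])
    px_ha = pixel_size_m * pixel_size_m / 10_000.0
    pixel_counts = np.bincount(labeled.labels.ravel(), minlength=k + 1)[1:]
    sizes_ha = (pixel_counts * px_ha).tolist()
    total = float(pixel_counts.sum() * px_ha)
    return ParticleSummary(
        count=k,
        total_area_ha=total,
        average_size_ha=total / k,
        sizes_ha=sizes_ha,
    )


def count_new_patches(
    prev_cum_loss: BinaryRaster,
    new_loss: BinaryRaster,
    connectivity: int = 8,
) -> int:
    """Count fresh-location loss patches.

    A patch of ``new_loss`` counts as "new independent" when none of its
    pixels is an 8-neighbour of (or overlaps) previously accumulated loss
    — i.e. it appears in a fresh location rather than extending an
    existing loss cluster.
    """
    if prev_cum_loss.shape != new_loss.shape:
        raise ValueError(
            f"shape mismatch: {prev_cum_loss.shape} vs {new_loss.shape}"
        )
    labeled = label_components(new_loss, connectivity=connectivity)
    k = labeled.n_patches
    if k == 0:
        return 0
    near_prev = ndimage.binary_dilation(prev_cum_loss.bool(), structure=_STRUCTURES[8])
    touched = np.unique(labeled.labels[near_prev])
    touched = touched[touched > 0]
    return k - len(touched)
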