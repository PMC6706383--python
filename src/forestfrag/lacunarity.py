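"""Fixed-grid lacunarity and the Tug-of-War second-moment sketch.

Lacunarity at box side r is the normalised second moment of box
occupancies on a fixed non-overlapping grid,

    Lambda(r) = N(r) * Z^2 / L^2,
    Z^2 = sum_i p(r, i)^2,       L^2 = (sum_i p(r, i))^2,

where p(r, i) counts occupied sites in the i-th box and N(r) is the
total number of grid boxes (empty ones included).  Lambda(r) >= 1 for
any non-empty mask by Cauchy-Schwarz, equals 1 for a translation-
invariant filled mask at divisor scales, and grows with heterogeneity —
large values indicate a chaotic, gappy spatial arrangement.

The Tug-of-War estimator replaces the exact Z^2 with a randomised
second-moment (AMS) sketch: (sum_i sigma_i p_i)^2 with Rademacher signs
sigma_i is unbiased for Z^2; accuracy comes from averaging s1
independent sketches and robustness from taking the median over s2
groups.  It is retained both for fidelity to the method's name and for
streaming-scale inputs; the exact moment is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .raster import BinaryRaster

__all__ = [
    "SketchParams",
    "LacunarityProfile",
    "default_lacunarity_scales",
    "box_occupancy",
    "exact_lacunarity",
    "tow_second_moment",
    "tow_lacunarity",
    "lacunarity_profile",
]


@dataclass
class SketchParams:
    """Tug-of-War sketch sizes: mean over s1 sketches, median over s2
    groups (s2 odd keeps the median unambiguous)."""

    s1: int = 100
    s2: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s1 < 1 or self.s2 < 1:
            raise ValueError(f"s1 and s2 must be >= 1, got s1={self.s1}, s2={self.s2}")


@dataclass
class LacunarityProfile:
    scales: list[int]
    lambdas: list[float]
    aggregate: float
    method: str = "exact"
    sketch_params: Optional[SketchParams] = None


def default_lacunarity_scales(shape: tuple[int, int]) -> list[int]:
    """Dyadic box sides from 2 up to min(H, W)/4."""
    top = min(shape) // 4
    scales = []
    r = 2
    while r <= top:
        scales.append(r)
        r *= 2
    return scales or [2]


def box_occupancy(mask: BinaryRaster, r: int) -> np.ndarray:
    """Occupancy counts p(r, i) on a fixed grid anchored at (0, 0).

    Partial boxes at the right/bottom edges are included; empty boxes
    contribute zeros.
    """
    fg = mask.bool()
    h, w = fg.shape
    if not 1 <= r <= min(h, w):
        raise ValueError(f"box side must lie in [1, {min(h, w)}], got {r}")
    nh = -(-h // r)
    nw = -(-w // r)
    if nh * r != h or nw * r != w:
        padded = np.zeros((nh * r, nw * r), dtype=bool)
        padded[:h, :w] = fg
        fg = padded
    return fg.reshape(nh, r, nw, r).sum(axis=(1, 3)).ravel().astype(np.int64)


def exact_lacunarity(mask: BinaryRaster, r: int, occupied_only: bool = False) -> float:
    """Lambda(r) from the exact second moment.

    ``occupied_only`` restricts N(r) to boxes with p > 0 (an alternative
    normalisation some plugins use); the default counts all grid boxes.
    """
    p = box_occupancy(mask, r).astype(float)
    total = p.sum()
    if total == 0:
        raise ValueError("exact_lacunarity: empty mask (L^2 = 0)")
    n = int((p > 0).sum()) if occupied_only else p.size
    return float(n * np.sum(p**2) / total**2)


def tow_second_moment(
    occupancies: Sequence[int] | np.ndarray,
    s1: int,
    s2: int,
    seed: int,
) -> float:
    """Median-of-means AMS sketch of Z^2 = sum p_i^2.

    Draws s2*s1 independent Rademacher sign vectors from the seeded
    generator; each sketch (sum_i sigma_i p_i)^2 is unbiased for Z^2.
    """
    if s1 < 1 or s2 < 1:
        raise ValueError(f"s1 and s2 must be >= 1, got s1={s1}, s2={s2}")
    p = np.asarray(occupancies, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(s2, s1, p.size)) * 2 - 1
    z = signs @ p                      # (s2, s1)
    group_means = np.mean(z**2, axis=1)
    return float(np.median(group_means))


def tow_lacunarity(mask: BinaryRaster, r: int, params: SketchParams) -> float:
    """Lambda(r) with the sketched second moment in place of Z^2."""
    p = box_occupancy(mask, r)
    total = p.sum()
    if total == 0:
        raise ValueError("tow_lacunarity: empty mask (L^2 = 0)")
    z2 = tow_second_moment(p, params.s1, params.s2, params.seed)
    return float(p.size * z2 / float(total) ** 2)


def lacunarity_profile(
    mask: BinaryRaster,
    scales: Sequence[int] | None = None,
    method: str = "exact",
    sketch_params: Optional[SketchParams] = None,
) -> LacunarityProfile:
    """Lambda(r) over a scale set, plus the arithmetic-mean aggregate
    used as the per-layer scalar."""
    if method not in ("exact", "tug_of_war"):
        raise ValueError(f"method must be 'exact' or 'tug_of_war', got {method!r}")
    if scales is None:
        scales = default_lacunarity_scales(mask.shape)
    scales = [int(r) for r in scales]
    if not scales:
        raise ValueError("empty scale set")
    if method == "tug_of_war":
        params = sketch_params or SketchParams()
        # decorrelate scales while keeping the profile reproducible
        lambdas = [
            tow_lacunarity(mask, r, SketchParams(params.s1, params.s2, params.seed + k))
            for k, r in enumerate(scales)
        ]
    else:
        params = None
        lambdas = [exact_lacunarity(mask, r) for r in scales]
    return LacunarityProfile(
        scales=scales,
        lambdas=lambdas,
        aggregate=float(np.mean(lambdas)),
        method=method,
        sketch_params=params,
    )
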