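"""Min-max standardisation and Spearman rank correlation.

Particle and fractal metrics have incommensurate units, so time series
are rescaled onto [0, 1] before joint plotting:

    standard value = (Vnom - Vmin) / (Vmax - Vmin).

Associations between metric series are summarised by Spearman's rank
correlation (Pearson correlation of mean-ranked data); no p-values are
attached.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["MetricSeries", "standardize", "minmax", "spearman_rho"]

log = logging.getLogger(__name__)


@dataclass
class MetricSeries:
    name: str
    year_labels: list
    values: list[float]
    standardized: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if len(self.values) != len(self.year_labels):
            raise ValueError(
                f"{self.name}: {len(self.values)} values for "
                f"{len(self.year_labels)} year labels"
            )


def minmax(values: Sequence[float]) -> np.ndarray:
    """(V - Vmin) / (Vmax - Vmin); a constant series maps to zeros
    (with a logged warning) so batch reporting never aborts."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need at least 2 values to standardize, got {v.size}")
    vmin, vmax = float(np.min(v)), float(np.max(v))
    if vmax == vmin:
        log.warning("constant series (all values %g): standardized to zeros", vmin)
        return np.zeros_like(v)
    return (v - vmin) / (vmax - vmin)


def standardize(series: MetricSeries) -> MetricSeries:
    """Return the series with its standardized values filled in."""
    return replace(series, standardized=minmax(series.values).tolist())


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation; ties get mean ranks.

    Constant input leaves the coefficient undefined: NaN is returned
    with a warning rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("constant input: Spearman's rho undefined, returning NaN")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, _ = stats.spearmanr(x, y)
    return float(rho)
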