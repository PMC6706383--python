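"""Yearly analysis pipeline: masks -> metrics -> standardized report.

For each year t the three-layer stack yields three masks — that year's
loss, the cumulative loss up to t, and the remaining tree cover
(baseline minus cumulative loss; regeneration is reported as its own
layer and never re-added, since the data model only carries cumulative
gain) — and every requested metric is computed on each.  Metric series
are min-max standardized across years per (layer, metric), and a
Spearman correlation matrix over the series is attached.  All masks
share one raster extent and pixel size; mixed shapes are refused.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .boxcount import compute_ffi
from .lacunarity import SketchParams, lacunarity_profile
from .lcfd import lcfd_map
from .norm import minmax, spearman_rho
from .particle import count_new_patches, label_components, summarize_particles
from .raster import BinaryRaster, ForestLayerSet

__all__ = [
    "PipelineConfig",
    "TimeSeriesReport",
    "derive_yearly_masks",
    "run_timeseries",
    "write_report",
]

log = logging.getLogger(__name__)

ALL_METRICS = (
    "area_ha",
    "patch_count",
    "average_size_ha",
    "ffi",
    "d_area",
    "d_perimeter",
    "mean_lcfd",
    "lambda_aggregate",
)

LAYERS = ("tree_cover", "loss", "cumulative_loss", "gain")


@dataclass
class PipelineConfig:
    metrics: Sequence[str] = ALL_METRICS
    connectivity: int = 8
    boxcount_scales: Optional[list[int]] = None      # None -> dyadic default
    lcfd_scales: Optional[list[int]] = None          # None -> odd 3..33
    lcfd_border_policy: str = "exclude"
    lacunarity_scales: Optional[list[int]] = None    # None -> dyadic default
    lacunarity_method: str = "exact"
    sketch_s1: int = 100
    sketch_s2: int = 5
    seed: int = 0
    readd_gain: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.metrics) - set(ALL_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}; choose from {ALL_METRICS}")

    def as_text(self) -> str:
        buf = io.StringIO()
        for key, value in vars(self).items():
            buf.write(f"{key} = {value}\n")
        return buf.getvalue()


@dataclass
class TimeSeriesReport:
    table: pd.DataFrame          # long: year, layer, metric, value, standardized
    spearman: pd.DataFrame       # series x series rank correlations
    config: PipelineConfig
    log: list[str] = field(default_factory=list)


def derive_yearly_masks(
    layers: ForestLayerSet, year_index: int
) -> tuple[BinaryRaster, BinaryRaster, BinaryRaster]:
    """(tree_cover_t, loss_t, cumulative_loss_t) for 1-based year t."""
    t_max = layers.n_years
    if not 1 <= year_index <= t_max:
        raise ValueError(f"year index {year_index} outside 1..{t_max}")
    codes = layers.loss_year.values
    if int(codes.max(initial=0)) > t_max:
        raise ValueError(
            f"loss-year code {int(codes.max())} exceeds the {t_max} labelled years"
        )
    px = layers.pixel_size_m
    loss_t = (codes == year_index).astype(np.uint8)
    cum_t = ((codes >= 1) & (codes <= year_index)).astype(np.uint8)
    cover_t = (layers.cover_baseline.mask.astype(bool) & ~cum_t.astype(bool)).astype(np.uint8)
    return (
        BinaryRaster(cover_t, px),
        BinaryRaster(loss_t, px),
        BinaryRaster(cum_t, px),
    )


def _metrics_for_mask(
    mask: BinaryRaster, config: PipelineConfig, messages: list[str], tag: str
) -> dict[str, float]:
    """Requested metrics on one mask; empty masks record NaNs and a log
    entry instead of aborting the run."""
    out: dict[str, float] = {}
    wanted = set(config.metrics)
    empty = not mask.mask.any()

    if wanted & {"area_ha", "patch_count", "average_size_ha"}:
        labeled = label_components(mask, connectivity=config.connectivity)
        summary = summarize_particles(labeled, mask.pixel_size_m)
        if "area_ha" in wanted:
            out["area_ha"] = summary.total_area_ha
        if "patch_count" in wanted:
            out["patch_count"] = float(summary.count)
        if "average_size_ha" in wanted:
            out["average_size_ha"] = summary.average_size_ha

    fractal = wanted & {"ffi", "d_area", "d_perimeter", "mean_lcfd", "lambda_aggregate"}
    if fractal and empty:
        for name in fractal:
            out[name] = float("nan")
        messages.append(f"{tag}: empty mask, fractal metrics recorded as missing")
        return out

    if wanted & {"ffi", "d_area", "d_perimeter"}:
        res = compute_ffi(mask, config.boxcount_scales)
        if "ffi" in wanted:
            out["ffi"] = res.ffi
        if "d_area" in wanted:
            out["d_area"] = res.d_area
        if "d_perimeter" in wanted:
            out["d_perimeter"] = res.d_perimeter
    if "mean_lcfd" in wanted:
        res = lcfd_map(mask, config.lcfd_scales, border_policy=config.lcfd_border_policy)
        out["mean_lcfd"] = res.mean
    if "lambda_aggregate" in wanted:
        profile = lacunarity_profile(
            mask,
            config.lacunarity_scales,
            method=config.lacunarity_method,
            sketch_params=SketchParams(config.sketch_s1, config.sketch_s2, config.seed),
        )
        out["lambda_aggregate"] = profile.aggregate
    return out


def run_timeseries(layers: ForestLayerSet, config: Optional[PipelineConfig] = None) -> TimeSeriesReport:
    """Compute every requested metric for every year and layer, then
    standardize per metric series and correlate the series."""
    config = config or PipelineConfig()
    messages: list[str] = []
    rows: list[dict] = []

    for t in range(1, layers.n_years + 1):
        year = layers.years[t - 1]
        cover_t, loss_t, cum_t = derive_yearly_masks(layers, t)
        if config.readd_gain:
            # crude alternative: union the (cumulative) gain back into cover
            cover_t = BinaryRaster(
                (cover_t.mask.astype(bool) | layers.gain_cumulative.mask.astype(bool)).astype(np.uint8),
                cover_t.pixel_size_m,
            )
        for layer_name, mask in (
            ("tree_cover", cover_t),
            ("loss", loss_t),
            ("cumulative_loss", cum_t),
        ):
            values = _metrics_for_mask(mask, config, messages, f"{layer_name}@{year}")
            for metric, value in values.items():
                rows.append(
                    {"year": year, "layer": layer_name, "metric": metric, "value": value}
                )

    # Gain is a single cumulative layer: one row block at the final year.
    gain_vals = _metrics_for_mask(
        layers.gain_cumulative, config, messages, f"gain@{layers.years[-1]}"
    )
    for metric, value in gain_vals.items():
        rows.append(
            {"year": layers.years[-1], "layer": "gain", "metric": metric, "value": value}
        )

    table = pd.DataFrame(rows, columns=["year", "layer", "metric", "value"])
    table["standardized"] = np.nan
    for (layer_name, metric), group in table.groupby(["layer", "metric"]):
        finite = group["value"].notna()
        if finite.sum() >= 2:
            idx = group.index[finite]
            table.loc[idx, "standardized"] = minmax(group.loc[idx, "value"].to_numpy())

    series: dict[str, np.ndarray] = {}
    for (layer_name, metric), group in table.groupby(["layer", "metric"]):
        vals = group.sort_values("year")["value"].to_numpy(dtype=float)
        if np.isfinite(vals).all() and len(vals) >= 3 and not np.all(vals == vals[0]):
            series[f"{layer_name}/{metric}"] = vals
    names = sorted(series)
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                rho = spearman_rho(series[a], series[b])
                corr.iloc[i, j] = corr.iloc[j, i] = rho

    for msg in messages:
        log.info(msg)
    return TimeSeriesReport(table=table, spearman=corr, config=config, log=messages)


def write_report(report: TimeSeriesReport, outdir: Path | str) -> None:
    """report.csv + spearman.csv + run_config.txt + run.log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(outdir / "report.csv", index=False, float_format="%.10g")
    report.spearman.to_csv(outdir / "spearman.csv", float_format="%.10g")
    (outdir / "run_config.txt").write_text(report.config.as_text())
    (outdir / "run.log").write_text("\n".join(report.log) + ("\n" if report.log else ""))
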