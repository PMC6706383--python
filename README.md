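# forestfrag

Particle and fractal analysis of forest fragmentation from binary raster
time series.

Deforestation rarely removes forest uniformly: it either gnaws at the
edge of existing clearings (compact logging) or opens new, scattered
holes. `forestfrag` quantifies both the amount and the *arrangement* of
forest change from the standard three-layer forest-change data model — a
baseline tree-cover mask, a per-pixel loss-year layer, and a cumulative
regeneration layer — producing per-year, per-layer tables of:

- **Particle statistics** — patch count, total area (ha), average patch
  size, and the number of loss patches appearing in fresh locations
  (components with no 8-neighbour contact with previously accumulated
  loss).
- **FFI, the Fractal Fragmentation Index** — the box-counting dimension
  of the area set minus that of its 4-neighbour inner-boundary perimeter
  set, `FFI = D_A − D_P`, each `D` the OLS slope of `log N(ε)` against
  `log(1/ε)` on a fixed top-left-anchored grid. A compact object has
  `FFI` near 1, fragmented dust near 0, and a single pixel exactly 0.
- **LCFD, the Local Connected Fractal Dimension** — at each foreground
  pixel, the slope of `log M(ε)` vs `log ε`, where `M(ε)` is the mass of
  the 8-connected component of the pixel inside the `ε×ε` window centred
  on it. Exactly 1.0 on a straight line, 2.0 inside a filled region; the
  per-layer scalar is the mean over foreground pixels.
- **Lacunarity** — `Λ(r) = N(r)·Z²/L²` with `Z² = Σᵢ p(r,i)²` and
  `L² = (Σᵢ p(r,i))²` over the occupancies `p(r,i)` of a fixed grid of
  `r×r` boxes (empty boxes included in `N`). `Λ ≥ 1` always; larger
  means a gappier, more heterogeneous mosaic. The exact second moment is
  the default; a seeded Tug-of-War (median-of-means AMS) sketch of `Z²`
  is available for very large inputs.

Metric series are min–max standardized onto [0, 1] for joint plotting
and cross-correlated with Spearman's rank coefficient. A seeded
synthetic scenario generator produces three-layer stacks with exact
ground truth (patch counts, sizes, fresh-location counts) for testing
and calibration.

Rasters must already be in a metric projection; the package reads and
writes single-band GeoTIFF/TIFF (pixel size via the ModelPixelScale tag,
default 30 m) and performs **no reprojection**.

## Worked example

```python
import forestfrag as ff

cfg = ff.ScenarioConfig(shape=(96, 96), n_years=6, patches_per_year=8, seed=7)
layers, truth = ff.generate_scenario(cfg)
report = ff.run_timeseries(layers, ff.PipelineConfig(
    metrics=("area_ha", "patch_count", "average_size_ha", "ffi", "lambda_aggregate"),
))
t = report.table
print(t[(t.layer == "tree_cover") & (t.metric.isin(["area_ha", "ffi", "lambda_aggregate"]))]
      .pivot(index="year", columns="metric", values="value").round(4))
```

```
metric  area_ha     ffi  lambda_aggregate
year
1        554.58  0.4506            1.2775
2        544.86  0.4344            1.2874
3        535.14  0.4120            1.2984
4        524.07  0.3716            1.3101
5        513.72  0.3405            1.3190
6        501.75  0.3123            1.3305
```

Reading the table: the remaining tree cover loses ~53 ha over six
simulated years (554.6 → 501.8 ha); its FFI falls from 0.45 to 0.31 —
the cover is becoming more fragmented, not merely smaller — while its
lacunarity rises (1.28 → 1.33), i.e. the holes make the mosaic more
heterogeneous. `report.spearman` confirms the three series are perfectly
rank-correlated over this monotone run (ρ = +1 between cover area and
FFI, both declining together).

The same pipeline runs from the shell:

```sh
forestfrag synth --out scenario/ --shape 96x96 --years 6 --seed 7
forestfrag analyze --stack scenario/ --out report/
forestfrag metrics report_mask.tif          # single-mask metrics as JSON
```

`analyze` writes `report.csv` (long format: year, layer, metric, value,
standardized), `spearman.csv`, `run_config.txt` and `run.log`.

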