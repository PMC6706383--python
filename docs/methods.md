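# Methods

This note documents the estimators, their numerical conventions and
defaults, what the synthetic generator does and does not emulate, and
the package's known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and coordinate conventions

All analysis operates on 2D `{0,1}` masks with a square pixel whose side
is carried in metres (default 30 m, the resolution of Landsat-derived
forest-change layers). Grids are row-major, 0-based, origin at the
top-left. A forest-change stack consists of a baseline cover mask, a
loss-year layer (code `t` = lost in year `t`, 0 = never lost) and one
cumulative gain layer; per-year gain is not part of the model, so the
pipeline reports gain as a single layer at the final year and never adds
it back into yearly tree cover (a `readd_gain` option unions the
cumulative gain into cover for sensitivity checks, nothing more).
Yearly masks are `loss_t = {code == t}`, `cum_loss_t = {1 ≤ code ≤ t}`,
`tree_cover_t = baseline \ cum_loss_t`. All layers of one run must share
shape and pixel size; mixed extents are refused because every estimator
below is scale- and extent-sensitive.

Inputs must already be metric; the package performs no reprojection.
Canopy binarization defaults to `>0` since near-binary layers are the
common case; a `>=t` mode covers canopy-percent inputs (the threshold is
a user choice, logged per run — no particular published threshold is
assumed).

## Particle analysis

Patches are connected components, 8-adjacency by default (matching the
8-neighbour rule used for local connectivity below; 4-adjacency is an
option). Areas are pixel counts × pixel area (ha). A loss patch counts
as a *fresh-location* ("new independent") patch when its one-pixel
8-dilation does not intersect previously accumulated loss. "Independent"
is operationalized here as non-adjacency; no minimum-size criterion is
applied, and no shape descriptors (circularity, Feret) are computed.

## Box counting and FFI

`N(ε)` counts occupied cells of a fixed, non-overlapping grid anchored
at the top-left corner; partial boxes at the right/bottom edges are
included. The dimension is the OLS slope of `log N(ε)` vs `log(1/ε)`;
`r²` is reported so degraded fits are visible. No grid-offset averaging
is performed, so counts are deterministic; the cost is translation
sensitivity of at most the number of boundary boxes per scale (tested as
a bound, not an equality).

Default scales are powers of two from 2 to `min(H, W)/4`. `ε = 1` is
excluded because `N(1)` is the raw pixel count and dominates the area
fit. The coarse end is capped at a quarter of the short side: coarser
grids cover any set with a handful of boxes and collapse the
perimeter-set slope toward the trivial floor, visibly biasing FFI (for a
filled 256×256 square the frame slope degrades from ~1.07 at cap 64 to
~1.14 at cap 128, dragging FFI from 0.93 to 0.86 against a closed-form
frame count of `4(256/ε − 1)`). Scales are fully configurable.

The perimeter set is the 4-neighbour inner boundary (a foreground pixel
with a background or out-of-image 4-neighbour). This choice makes the
single-pixel identity exact: a lone pixel is its own perimeter, both
slopes are 0, and `FFI = 0`.

## Local Connected Fractal Dimension

`M(ε)` is the size of the 8-connected component containing the seed
pixel, computed strictly inside the `ε×ε` window centred on the seed
(clipped at image borders; connectivity is decided only among in-window
pixels). "Connected" means standard Moore (8-neighbour) adjacency — the
one reading consistent with mass growing from the seed. The local
dimension is the OLS slope of `log M(ε)` vs `log ε`; the mass pre-factor
is the fit intercept. Default window sides are odd ε from 3 to 33
(FracLac-style), configurable.

For maps, the default border policy is `clip` (every foreground pixel
gets a value); for the per-layer scalar the default is `exclude` — pixels
whose largest window would be clipped are omitted from the mean and
histogram — because with clipping the analytic anchors (mean exactly 1.0
on a full-width line, 2.0 on a filled raster) hold only in the interior.
The scalar is the mean over counted foreground pixels; mean vs median is
a config-level choice with no published convention to match.

## Lacunarity and the Tug-of-War sketch

`Λ(r) = N(r)·Σp² / (Σp)²` over fixed-grid occupancies, with `N(r)` the
total number of grid boxes, empty ones included; partial edge boxes are
included as elsewhere. `Λ ≥ 1` for any non-empty mask (Cauchy–Schwarz),
`Λ = 1` exactly for a filled mask at divisor scales, and `Λ = N` when
all mass sits in one of `N` boxes. An `occupied_only` flag restricts
`N` to non-empty boxes for comparison with tools whose convention
differs. The per-layer scalar is the arithmetic mean of `Λ(r)` over
dyadic `r` from 2 to `min(H, W)/4`; the full profile is always emitted.

The Tug-of-War estimator replaces `Σp²` with a median of `s2` group
means of `s1` AMS sketches `(Σᵢ σᵢ pᵢ)²`, `σᵢ` i.i.d. Rademacher signs
from a seeded generator. Each sketch is unbiased for `Z²` with relative
variance `2(1 − Σp⁴/(Σp²)²)` — close to 2 for any many-box occupancy
vector — so the relative standard error is roughly `√2/√s1` per group;
at the default `s1 = 100, s2 = 5` a single seeded estimate carries a
spread of several percent, while the mean over many seeds converges to
the exact moment (tested over 1,000 seeds). The exact moment is the
default method; the sketch exists for streaming-scale inputs and for
fidelity to the method's name. Per-scale sketches use `seed + k` for the
k-th scale so profiles are reproducible yet decorrelated across scales.

**A direction worth stating explicitly:** for *fixed total area*,
fixed-grid lacunarity rewards concentration — compacting mass into fewer
boxes increases `Σp²` at every `r`, so a single compact square always
has higher `Λ` than the same area scattered into well-separated small
squares (e.g. one 12×12 square vs nine 4×4 squares in a 64×64 frame:
aggregate Λ 23.2 vs 16.4). Interpretations that equate "scattered" with
"more lacunar" hold only when scattering coincides with *gappier*
occupancy at the analysis scales (or with differing total area); they do
not follow from the definition above, and this package reports what the
definition gives.

## Standardization and correlation

Min–max standardization maps each per-year metric series onto [0, 1]
with endpoints attained. A constant series standardizes to zeros with a
logged warning rather than raising, so batch runs over degenerate
scenarios complete. Spearman's ρ is the Pearson correlation of
mean-ranked data; constant inputs yield NaN with a warning. No p-values
are attached.

## Synthetic scenario generator

The generator emulates the *structure* of real forest-change stacks,
with exact ground truth:

- Baseline cover: Gaussian noise smoothed with σ = 3 pixels and
  thresholded at the quantile realizing the requested cover fraction —
  spatially coherent, irregular cover, hit to within a pixel.
- Yearly loss: `patches_per_year` connected blobs grown by randomized
  dilation from a seed pixel, pixel counts drawn from a lognormal
  (defaults log-mean 2.5, log-sd 0.6 ≈ 15 px ≈ 1.3 ha at 30 m, between
  quiet `<1 ha` and intense `>1.5 ha` logging regimes). With probability
  `clustering_prob` the seed is drawn 8-adjacent to previously
  accumulated loss (compact regime); otherwise seed and growth are kept
  non-adjacent to all prior loss (fresh-location regime), so the
  fresh/extension status of every patch is exact by construction.
  Same-year patches are kept mutually non-adjacent so per-year particle
  statistics match truth exactly. Defaults: 14 years, cover fraction
  0.68, 12 patches/year on a 128×128 grid.
- Gain: a uniformly random subset of cumulative loss realizing
  `gain_fraction` (default 0.466 — under half the felled area regrows),
  emitted only as a cumulative end-of-period layer.

Everything is reproducible from a single integer seed
(`numpy.random.default_rng`). If cover is exhausted mid-run, the error
names the failing year.

What the generator does *not* emulate: terrain and ecological
covariates, spatial autocorrelation calibrated to any real landscape,
sensor noise, mixed pixels, or reprojection artifacts. Passing tests
therefore demonstrate correctness of the estimators and pipeline on
landscapes with known structure — not that any particular real-world
magnitude will be reproduced.

## Problem sizes and numerical notes

Tests and the acceptance script run on desk-scale inputs chosen to make
the mathematics exact or the oracles exhaustive: 101×101 analytic
anchors, ≤64×64 oracle-equivalence masks, and twenty 64×64 × 5-year
scenarios per generator condition. LCFD is the one quadratic-cost metric
(per-pixel, per-scale window labelling); for large rasters restrict
`lcfd_scales` or compute it on subsampled layers. OLS fits use
`numpy.polyfit`; `r² = 1` is reported for exactly collinear log–log
points (including the degenerate all-counts-equal case, where the slope
is 0). Dimension estimates on finite binary images are scale-window
dependent — values are comparable only across runs sharing extent and
scale set, which is why the pipeline refuses mixed shapes.

## Known limitations

- FFI is a whole-image index; it carries no information about regional
  variation within the raster.
- Box-counting and lacunarity use a single grid anchor; FracLac-style
  multi-origin averaging is deliberately out of scope.
- Gliding-box (overlapping window) lacunarity and multifractal spectra
  are not implemented.
- The LCFD scalar aggregates a distribution; masks with identical means
  can differ in histogram shape (the histogram is returned for this
  reason).
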