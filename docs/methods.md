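# Methods

This note documents the models, parameter choices and numerical
conventions behind `phasequant`, and what the synthetic validations do
and do not demonstrate about real data.

## Synthetic disc generator

The generator renders a two-compartment epithelium: nuclei are hard
discs placed by rejection sampling (no overlap; bounded retries, default
1000 per nucleus, raising an error when the geometry is too dense)
inside two disjoint polygons standing in for the wing pouch and hinge.
Channel values are purely generative:

```
pixel = background + nuclear_contribution + N(0, noise_sd), clipped at 0
```

with per-channel nuclear contributions: constant DAPI per nucleus
(optionally ramping 1×→2× across S phase to mimic DNA replication; off
by default), FUCCI GFP/RFP means per phase, and
`base_intensity × phase_profile[phase] × pouch_multiplier` for marker
channels.

Defaults (all configurable) describe a densely populated disc imaged at
confocal resolution and were chosen once as field-typical values:

| parameter | default | rationale |
|---|---|---|
| pixel size | 0.25 µm/px | typical confocal sampling |
| nucleus radius | 1.0 ± 0.1 µm | wing-disc nuclei are ~2 µm across |
| n nuclei / coverage | 500, ~40% of the compartments | dense epithelium |
| FUCCI low/high | 10 / 100 a.u. | cleanly separable reporter states |
| marker base intensity | 100 a.u. | mid-range of an 8-bit-like scale |
| phase proportions | (0.30, 0.20, 0.20, 0.30) | a proliferating tissue |
| marker phase profile | (0.85, 1.30, 1.25, 0.90) | early-S-peaked acetylation dynamics |
| background / noise sd | 2 / 5 a.u. | low camera floor, ~5% of dynamic range |

What the generator does **not** emulate: out-of-focus light, shading
and chromatic aberration, nucleus shape irregularity and clumping,
intensity variation within and between nuclei beyond additive Gaussian
noise, mitotic figures (excluded from the analysis by design), and any
spatial patterning of phases. Passing the recovery tests therefore
shows the *analysis operations* are correct and unbiased under
realistic noise — not that segmentation or classification would reach
the same accuracy on arbitrary microscope data.

The count simulator draws negative-binomial counts
(Var = µ + αµ², α = 0 degenerating to Poisson) over four region
categories with per-category true log2 fold changes applied to the
knockdown condition, and per-sample means scaled by the depth implied
by the spike-in and H3 totals. Default: 2000 regions
(800/200/200/800 across shared / unique-WT / unique-KD / no-peak
bins), baseline mean 200, dispersion 0.05, two replicates per
condition, and mildly unequal depths (±10%) so normalization is
actually exercised.

## Segmentation conventions

* **Rolling ball**: grayscale morphological background estimation. For
  radii above 10 px the background is computed on a min-filtered,
  downscaled copy and bilinearly upsampled (the same shrink strategy the
  original tool uses); this is exact for flat backgrounds and accurate
  for smooth ones, at a tiny fraction of the cost of the full-resolution
  ball. Output is clipped non-negative.
* **CLAHE**: delegated to contrast-limited adaptive histogram
  equalization with tile edge = block size, and the slope limit mapped
  to a histogram clip at `max_slope / n_bins` of the tile mass (slope 1
  ≈ identity, slope 3 = the published setting). Input is rescaled to
  [0, 1] by its min/max and the output stays in [0, 1]; constant images
  are returned unchanged. Tile interpolation can reorder pixels within
  one histogram bin; rank order holds to that quantization.
  "Block size 127" is read as the tile edge length in pixels — tool
  implementations differ subtly here, which is documented rather than
  resolved.
* **Thresholding**: histograms use one bin per gray level for
  8-bit-like integer images and 256 equal bins over [min, max]
  otherwise, accepting float input while matching 8-bit tool behaviour.
  Otsu maximizes between-class variance with exact plateau ties broken
  at the plateau midpoint (so a two-delta histogram thresholds between
  its modes). Moments is Tsai's closed form: preserve the first three
  gray-level moments with a two-level image, then cut the cumulative
  histogram at the lower level's mass fraction. With a dark background
  the foreground is `image > threshold`. Constant images raise — no
  threshold is defined.
* **Channel averaging** in the `averaged_otsu` workflow is sequential
  pairwise averaging, `(((DAPI+GFP)/2+RFP)/2+marker)/2`, mirroring
  repeated two-image averaging in the original tool chain. The two
  nuclear-mask variants (Moments for EdU work, Otsu for phase
  distributions) are kept as distinct presets.
* **Polygons** are rasterized by pixel centers (pixel *(i, j)* covers
  `[i, i+1) × [j, j+1)`); polygons are assumed simple, where even-odd
  and nonzero fill rules agree.

## FUCCI thresholds and classification

Threshold derivation averages the per-nucleus mean intensities of the
reference early S nuclei (default five). Averaging nucleus means rather
than pooled pixels makes the estimate robust to nucleus-size variation;
the pooled variant is exposed as an option since the original
description does not disambiguate. Classification applies the
four-quadrant rule per pixel with `<=` winning at exact equality, uses
one threshold pair per image, and leaves mitotic cells unmodelled.

A consequence worth stating plainly: a threshold placed at the *mean*
of the reporter-negative reference population bisects that population
whenever noise is symmetric, so at any nonzero noise roughly half the
early-S pixels sit above it. The rule is exact at zero noise (where the
boundary convention sends equality to early S), and the zero-noise
validations use thresholds derived this way. Noisy-disc validations
instead use `validation_thresholds`, which places the cutoffs midway
between the generator's low and high reporter levels — the maximally
noise-robust operating point, available only because the generator's
levels are known. On real images the reference-nucleus rule works
because negative-population intensities are skewed and the analyst
verifies thresholds against EdU incorporation patterns; the midpoint
choice is the synthetic analogue of that verification step.

## Intensity statistics

Phase normalization defaults to `mean_of_phases` (each phase's mean
divided by the average of the four phase means, so the values average
to 1); `sum_of_phases` (relative contribution to the summed signal) is
exposed as an alternative, since both normalizations appear in verbal
descriptions of this analysis and they differ only by a factor of 4.
Missing phases propagate as NaN and are excluded from the denominator.

ROI ratios are (mean of per-ROI means)/(mean of per-ROI means); ROIs
are inputs, with a seeded helper that places three non-overlapping
15 × 15 µm squares per compartment as a stand-in for manual placement.
The EdU/DAPI statistic uses the union denominator
|EdU ∩ DAPI ∩ pouch| / |(EdU ∪ DAPI) ∩ pouch| so it is a bounded
fraction; an intersection-denominator variant is available. Region
areas are rasterized pixel counts × pixel area. Cross-disc aggregation
is a plain mean; group significance testing is out of scope.

## CUT&Tag quantification

Coordinates are BED-style 0-based half-open. Peak merging uses strict
(≥ 1 bp) overlap — bookended peaks share zero bases and stay separate —
and a merged peak is shared when it overlaps at least one peak from
each condition. Bins overlapping no peak at all are the no-peak
category. The interval code is a small sorted-array implementation
validated exactly against a brute-force oracle.

Size factors combine a spike-in component (sample total ÷ a reference
depth, by default the geometric mean of the observed totals) with an H3
component (median-of-ratios over the matched total-H3 library, zero
rows excluded), multiplied. The reference depth is an explicit constant
of the analysis (`spikein_reference`): factors are computed once and
reused, which makes normalized counts exactly invariant to rescaling
any one sample's counts together with its spike-in total. H3 matching
is explicit via a sample-sheet column; nothing is inferred.

The differential test fits, per region, a negative-binomial GLM with
log link, design `~ replicate + condition` (two-level fixed effects)
and `log(size factor)` offsets; the p-value is a two-sided Wald test on
the condition coefficient, BH-adjusted across all tested regions of a
run (not per category). Regions with basemean ≤ 25 normalized counts
are discarded before testing; significance is padj < 0.1.

Dispersion uses a per-region method-of-moments estimate on normalized
counts — averaged over conditions, then floored at the dataset *median*
of the per-region estimates (and at 1e-8). The median floor matters:
with two replicates per condition the raw moment estimate collapses to
zero for a sizable minority of null regions purely by sampling
accident, which inflates their Wald statistics ~3-fold and breaks
false-discovery control. Flooring at the dataset-typical dispersion
removes that failure mode while leaving power essentially at the level
achievable with oracle dispersions; no dispersion trend or empirical-
Bayes shrinkage is modelled, and exact dispersion values are not a goal
of this implementation — direction and aggregate behaviour are.

LFC shrinkage is a ridge factor under a zero-centered normal prior,
`shrunk = raw × σ²/(σ² + se²)`, with prior sd σ set to the 95% quantile
of |raw LFC| over tested regions (floored at 1e-6). This guarantees
|shrunk| ≤ |raw| for every region. A cross-check test confirms that raw
LFCs agree per-region with an independent NB differential
implementation (pyDESeq2) up to the normalization gauge, which that
tool re-derives internally while this pipeline fixes it externally.

## Problem sizes and determinism

Validation runs use 10 discs of 500 nuclei for profile and ratio
recovery, 5 noise-free discs for phase fractions, 2000-region count
simulations (5 seeds for the null false-discovery check), 200–500
random instances for the exact oracle comparisons, and a reduced
(~160-region) configuration for the byte-determinism check — sizes at
which Monte-Carlo error is comfortably below each stated tolerance.
All randomness flows from `numpy.random.default_rng` seeds carried in
the specs; identical configurations produce bit-identical arrays and
byte-identical output tables (tables use a fixed float format and a
provenance header with a hash over the scientific parameters only).

At these conditions the measured power of the differential test at
|log2FC| = 1 (basemean 200, dispersion 0.05, 2 vs 2) is ~0.75, recorded
as a regression value; the null fraction of padj < 0.1 calls is below
0.01.

## Known limitations

* Per-pixel (not per-cell) statistics throughout; touching nuclei are
  never split, matching the analysis being reproduced but limiting
  reuse for per-cell questions.
* The rolling-ball downscaling approximation can underestimate sharp
  background gradients; radii ≤ 10 px run at full resolution.
* The moment-of-moments dispersion with a median floor is deliberately
  simpler than trend-based empirical-Bayes machinery; p-values are
  asymptotic Wald with 4 samples and should be read through the BH
  filter, not individually.
* The synthetic generator's simplifications listed above mean real-data
  performance of segmentation and classification must be established on
  real images; the package validates correctness of the computations,
  not microscope-level robustness.
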