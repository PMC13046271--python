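# phasequant

Cell cycle phase-resolved quantification of nuclear signals in
*Drosophila* wing imaginal disc images, with a companion genomics track
for CUT&Tag differential enrichment.

## The problem

Histone modifications such as H3K27ac are not static: their levels can
change within a single cell cycle. Measuring this in an intact tissue
requires (1) segmenting nuclei in multi-channel confocal images, (2)
assigning every nuclear pixel a cell cycle phase from the FUCCI reporter
pair, (3) summarizing marker intensity per phase and per tissue
compartment, and (4) checking, by quantitative CUT&Tag, whether genomic
modification levels change when the cell cycle is blocked. `phasequant`
implements this analysis as a tested Python library, together with a
synthetic-data generator that renders disc images and count matrices
with known ground truth so every stage can be validated without any
external data.

## The model

**FUCCI classification.** Two degradable reporters encode the phase:
GFP-E2F1 (high in G1/G2) and RFP-CycB (high in late S/G2). With a
threshold pair *(t<sub>G</sub>, t<sub>R</sub>)* derived from the average
intensity of five reference early S-phase nuclei, each nuclear pixel is

| GFP > t<sub>G</sub> | RFP > t<sub>R</sub> | phase |
|---|---|---|
| yes | yes | G2 |
| yes | no  | G1 |
| no  | no  | early/mid S |
| no  | yes | late S |

**Segmentation** follows the ImageJ-style recipes: rolling-ball
background subtraction (r = 100 px), CLAHE (block 127, 256 bins, max
slope 3), automatic thresholding by Otsu or by the moment-preserving
(Tsai) method; EdU masks use a Gaussian blur (σ = 2 px) before
thresholding.

**Per-disc statistics**: phase-normalized marker means
(mean intensity per phase ÷ average over the four phases), pouch/hinge
ROI intensity ratios from three 15 × 15 µm ROIs per compartment,
EdU/DAPI area fractions, mean intensities and region areas.

**CUT&Tag differential.** Regions are categorized as peaks shared
between wild type and knockdown, unique to either, or 500-bp bins with
no called peak. Counts are normalized by per-sample size factors
*s = (spike-in total / reference depth) × H3 median-of-ratios factor*
and tested per region with a negative-binomial GLM
(`~ replicate + condition`, Wald test), discarding regions with
basemean ≤ 25, adjusting p-values by Benjamini–Hochberg (significance
padj < 0.1), and shrinking log2 fold changes under a zero-centered
normal prior.

## Worked example

`examples/03_phase_profiles_and_ratios.py` simulates a disc whose
H3K27ac phase profile is (0.85, 1.30, 1.25, 0.90) with a 2× pouch
multiplier, then recovers both from the image:

```
phase-normalized H3K27ac profile (generator, rescaled to mean 1):
  G1       0.792  (truth 0.791)
  EARLY_S  1.207  (truth 1.209)
  LATE_S   1.162  (truth 1.163)
  G2       0.839  (truth 0.837)
pouch/hinge ROI ratio: 1.970  (generator multiplier 2.0)
```

The normalized profile peaks in early S exactly as simulated — the
S-phase coupling of the acetylation mark — and the compartment ratio
recovers the simulated 2× enrichment within a few percent.
`examples/04_cuttag_differential.py` runs the genomics track on a
simulation with a +1 log2 fold change confined to shared peaks:

```
mean raw log2FC in shared peaks: 0.974
   category  n_tested  n_up  n_down  pct_up  pct_down
     shared       800   595       0    74.4       0.0
  unique_wt       200     4       3     2.0       1.5
no_peak_bin       800    21      22     2.6       2.8
```

Only the truly changed category lights up; the no-peak bins behave as
nulls. The other examples cover segmentation fidelity, phase-fraction
recovery and the end-to-end pipeline (`phasequant run`, which is also
available as a CLI with `simulate-disc`, `simulate-counts`, `segment`,
`classify`, `cuttag-diff` subcommands).

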