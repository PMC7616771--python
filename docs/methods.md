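# Methods

This note documents the models implemented in `marrowquant`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Brightfield color model and deconvolution

Chromogenic stains absorb light multiplicatively, so analysis is done in
optical density, `OD_c = log10(I0 / max(I_c, 1))` per RGB channel. The
intensity floor of 1 bounds the OD of saturated pixels at log10(I0) without
special-casing; the background intensity I0 defaults to 255 (clean glass in
an 8-bit image) and is configurable per stain model. In OD space a pixel's
color is the concentration-weighted sum of unit stain vectors (Beer–Lambert
linearity), and concentrations are recovered by inverting the 3×3 stain
matrix per pixel.

The bundled default stain matrix uses the standard published H-DAB
absorbance vectors — hematoxylin (0.650, 0.704, 0.286) and DAB
(0.269, 0.568, 0.778), each normalized to unit length — completed to an
invertible basis by the normalized cross product of the two measured
vectors. User-supplied vectors are accepted through JSON config; validation
rejects non-unit rows and rank-deficient matrices. Negative concentrations
(possible for pixels outside the dye gamut, e.g. noise) are clipped to zero
by default because stain amounts are physically non-negative; a `raw` mode
preserves them for diagnostics.

Although the assay pairs DAB with a nuclear counterstain, the counterstain
vector is simply the second row of the stain model and can be replaced, so
the pipeline is agnostic to which blue stain was actually used.

### Stain normalization

Batch-to-batch staining variation is compensated by per-stain linear
rescaling: each stain's concentration map is multiplied by (reference robust
max / source robust max), where the robust max is the 99th percentile over
tissue pixels. A percentile rather than the maximum resists hot pixels; a
per-stain scale preserves within-slide rank order exactly, which is the
property the downstream Otsu cutoff relies on. A stain with zero robust max
(absent stain) is left unscaled with a warning rather than dividing by zero.

## Tissue masking and positivity calling

Tissue is defined as pixels whose *total* OD (sum over the three channels)
exceeds 0.15; background glass sits near zero total OD, so any moderate
threshold separates them, and 0.15 is low enough to keep weakly stained
tissue. The threshold is configurable.

The positivity cutoff is chosen once per cohort: chromogen concentrations of
all tissue pixels of all slides are pooled and thresholded by Otsu's method
(256-bin histogram, the 8-bit convention; configurable). Pooling makes the
cutoff — and therefore between-slide comparisons — independent of any single
slide's staining intensity, and is order-invariant by construction. The Otsu
implementation scans interior bin edges, computes the between-class variance
from bin centers and counts, and breaks ties toward the lowest maximizing
edge; it is tested for exact agreement with an exhaustive-search oracle.
"Intensity distribution" is taken to mean the deconvolved chromogen
concentration distribution (the quantity the deconvolution step exists to
produce) rather than a raw channel.

## Tile heatmaps and per-field records

The slide is partitioned into an axis-aligned grid anchored at the top-left
pixel, with tile edge `round(tile_size_um / microns_per_pixel)` pixels
(default 256 µm). Partial edge tiles are kept and flagged so that per-tile
positive/tissue counts partition the slide exactly; consequently the
tissue-weighted mean of tile ratios equals the whole-slide positive ratio to
machine precision, an identity asserted in tests. Tiles with no tissue carry
a missing ratio rather than zero.

Per-field records use the same tiling at a configurable high-power-field
size. The default field is a square of the same area as a common 40×
objective field, 0.237 mm² (edge ≈ 487 µm), since field sizes differ between
microscopes. Both the positive-pixel ratio (headline) and the mean chromogen
concentration are emitted per field, as either may be the desired per-field
statistic.

Correlation against an external per-tile fibrosis-density map (e.g. a
machine-learned fibrosis severity index on the same grid) is Spearman rank
correlation over tiles where both values are present, requiring at least 3
paired tiles.

## Fluorescence quantifiers

### Nuclei counting

The counter follows the classic edge-detection chain: Gaussian smoothing
(σ = 2 px), gradient magnitude with hysteresis (canny), morphological
closing (disk radius 2) to close small gaps in edge rings, hole filling,
connected-component labeling, and a minimum-area filter (30 px²).

Hysteresis thresholds are *quantiles* of the gradient-magnitude
distribution (defaults 0.95 / 0.99), which makes the detector invariant to
exposure and camera gain. The quantiles sit high deliberately: true nuclear
edges occupy well under a percent of a typical field, so lower quantiles
(e.g. 0.7/0.9) land at the noise floor of the mostly-empty background and
flood the field with spurious edge fragments. The flip side, documented as a
limitation, is that a field containing *no* nuclei but nonzero noise has no
true edges for the quantiles to latch onto and can produce spurious
detections; constant (noise-free blank) images short-circuit to zero cells.
Empty wells should be excluded upstream.

Touching nuclei are not split — there is no watershed stage — so counts are
exact only for well-separated nuclei. The synthetic generator's
`allow_touching` flag exists to exercise this failure mode.

### Per-cell collagen and fold change

The default readout (`per_count`) divides the integrated collagen-1
intensity of the field by the nucleus count: the assay counts nuclei and
attributes the field's collagen equally to them, with no cytoplasm
segmentation. A `per_mask` mode (mean collagen within nuclei masks dilated
by 2 px) is provided for comparison. Fields with zero detected cells have no
defined per-cell value and are excluded with an error/warning rather than
reported as zero. Condition summaries are fold changes of mean per-cell
intensity over the untreated control condition; the ratio cancels any global
camera gain.

### Organoid stacks

Z-stacks are reduced by per-pixel maximum projection, denoised with a 3×3
median filter, and background-subtracted with a rolling ball (radius 50 px
by default), i.e. grayscale opening by a ball: smooth background wider than
the ball is removed while structures narrower than the ball are preserved.
The per-organoid statistic is the mean intensity within each labeled ROI.
The denoising filter and radius are configurable since assays differ in
scale; with the defaults, an ROI must be substantially narrower than the
ball (diameter ≲ ball radius) for its plateau to survive subtraction — the
ball's geometric rise under a gap of half-width w is R − sqrt(R² − w²),
which for R = 50 and w = 12 is under 1.5 intensity-fraction percent of R.

## Gene-set expression-fraction scores

For each cell the score is (UMIs on expressed set genes) / (UMIs on all
genes). Two conventions matter:

- The **numerator** uses only set genes passing the expressed-gene filter:
  total UMIs ≥ 50 summed over all cells of the compartment, with the filter
  recomputed independently for hematopoietic and stromal matrices (their
  depths differ, so a gene can be expressed in one compartment only).
- The **denominator** is the cell's unfiltered total, so scores are bounded
  in [0, 1], scale-free (multiplying a cell's counts by k changes nothing),
  and interpretable as the fraction of the cell's transcriptional output in
  the program.

Cells with zero total counts score missing (0/0 is undefined and such cells
are upstream QC failures), and set genes absent from the matrix are dropped
with a warning. Expressed-gene counts are also reported per category
(e.g. collagens / glycoproteins / proteoglycans) for compartment-level
summaries. Gene lists are user input (two-column CSV, `gene_id[,category]`);
the package does not ship curated biological lists.

Group comparisons are pairwise two-sided Wilcoxon rank-sum tests on the
per-cell scores with BH adjustment across pairs.

## Nonparametric statistics

- **Wilcoxon rank-sum**: exact permutation distribution when the combined
  sample size is ≤ 14 with no ties (≤ C(14,7) = 3432 assignments — cheap,
  and the regime where the normal approximation is weakest); otherwise the
  normal approximation with midrank tie correction and continuity
  correction. The result records which path ran. At the boundary size the
  two paths agree to |Δp| ≲ 0.012 (worst case over random draws). The test
  is unpaired throughout.
- **Benjamini–Hochberg**: step-up adjustment (tested against the literal
  min-over-suffix definition); Bonferroni available as an option. Note the
  step-up map is not idempotent on arbitrary inputs — re-adjusting an
  adjusted vector multiplies by m/j again — though constant adjusted
  vectors are fixed points.
- **Proteomics normalization**: log2(x+1) variance stabilization followed by
  per-protein min-max scaling to [0, 1]. Constant proteins map to 0 with a
  warning; all-missing proteins are an error. Because the downstream test is
  rank-based, the log base and the scaling are inert for inference — they
  exist to make abundances comparable for inspection and effect summaries.

## Synthetic generators: what they emulate, and what not

Each generator is a pure function of its spec (every random draw flows from
the spec seed through a named per-generator stream), so fixtures are
bit-reproducible within a build. Conventions chosen for testability:

- **IHC slides**: tissue is a centered rectangle covering the designed
  tissue fraction; positive pixels are an exact-count random subset of
  tissue pixels; noise is Gaussian in OD space (multiplicative in
  intensity, matching Beer–Lambert), so the deconvolution round trip stays
  analytically checkable; non-tissue background is exactly white with no
  noise, giving the tissue mask an unambiguous truth. Default concentration
  levels (chromogen 0.8 positive / 0.1 negative, counterstain 0.4) keep all
  channel intensities well above the quantization floor, bounding the
  8-bit round-trip error at ~0.005 OD.
- **Fluorescence fields**: nuclei are uniform disks of fixed radius (8 px)
  on a flat background; the collagen channel is spatially uniform. Disks
  are placed with a minimum boundary gap of 6 px — "non-touching" is defined
  relative to the detector's closing element (radius 2 bridges ~4 px), so
  smaller gaps would be morphologically touching — and centers stay
  radius + 8 px clear of the field border, emulating the standard exclusion
  of border-clipped cells (an edge ring that leaves the field cannot be
  closed). Placement is rejection sampling with a bounded retry budget.
- **Z-stacks**: the noisy 2-D truth image is constructed first, then each
  pixel's true value is assigned to one random slice with damped copies
  elsewhere, so the maximum projection equals the truth image *exactly*.
  ROI disks default to radius 12 px with generous (6-radius) spacing so
  rolling-ball halos do not interact.
- **UMI counts**: per cell type, counts are one multinomial draw per cell
  with the designed probability mass p_set spread evenly over set genes
  (50 set + 500 other genes, depth 10⁴ by default) — so the expected score
  equals p_set and column sums equal the depth exactly. Fixed depth per
  cell is the default for simple variance accounting; log-normal depths are
  available behind a flag.
- **Proteomics**: log2 abundances are Gaussian around protein-specific
  baselines (uniform on [3, 8] log2 units, within-group sd 0.5), with the
  first 20 % of proteins shifted by the designed log2 fold change in group
  B.

None of this emulates real morphology, texture, dropout, doublets, batch
effects, or the depth/width of real datasets. Passing tests therefore
demonstrate that the *computations* are correct and recover designed truth
under their stated assumptions — not that the pipelines are robust to the
full variability of clinical images or single-cell libraries.

## Problem sizes and numerical conventions

Verification cohorts are sized for a desktop run: 512×512 px slides (6 per
cohort for positive-fraction recovery), 50 fluorescence fields of 10–100
nuclei, 500 cells per type at depth 10⁴ for score recovery, 500 simulated
null datasets for type-I calibration. These sizes make binomial/rank
sampling error comfortably smaller than the asserted tolerances (e.g. the
score-recovery SE at depth 10⁴ over 500 cells is ~3×10⁻⁴ against a ±0.01
band).

Ties in Otsu's criterion break toward the lowest qualifying bin edge;
positive calls use strict inequality (concentration > cutoff); heatmap tiles
without tissue are missing, not zero; Wilcoxon p-values are capped at 1;
and all CSV outputs have stable column order with headers.

## Known limitations

- No automatic stain-vector estimation; wrong vectors silently misattribute
  stain (the `raw` clipping mode helps diagnose this).
- The pooled Otsu cutoff assumes the cohort's pooled distribution is
  meaningfully bimodal; a cohort of uniformly negative slides will still
  yield a cutoff and nonzero "positive" calls.
- The nuclei counter neither splits touching nuclei nor suppresses spurious
  detections in signal-free noisy fields.
- Rolling-ball subtraction flattens structures wider than the ball; organoid
  ROIs must be narrow relative to the chosen radius.
- Exact Wilcoxon is limited to tie-free samples of total size ≤ 14; with
  heavy ties at small n the normal approximation is the only path.
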