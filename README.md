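# marrowquant

Quantification pipelines for bone-marrow niche studies of myeloproliferative
neoplasms and myelofibrosis: chromogen-stain IHC positivity with spatial
heatmaps, fluorescence fibrosis-assay readouts, per-cell gene-set expression
scores on single-cell UMI counts, and the shared nonparametric statistics —
together with synthetic-data generators that carry exact ground truth, so
every stage is verifiable without access to patient material.

It is aimed at computational biologists quantifying marrow histology
(e.g. galectin-1 IHC against reticulin fibrosis), fibroblast-to-myofibroblast
transition (FMT) plates, organoid fibrosis stains, and stromal/hematopoietic
gene-set activity such as extracellular-matrix (ECM), chemokine and
niche-support-factor (NSF) programs.

## What it computes

**IHC positivity** (`stain_deconv`, `ihc_quant`). Brightfield RGB is
converted to optical density, OD_c = log10(I₀ / I_c), where stain amounts mix
linearly (Beer–Lambert). Per pixel, the 3×3 unit stain matrix **M** (DAB
chromogen, hematoxylin-like counterstain, orthogonal complement) is inverted:

    OD = c · M    ⇒    c = OD · M⁻¹

giving a chromogen concentration map. A *single* positivity cutoff for a
whole cohort is chosen by Otsu's method (maximum between-class variance) on
the pooled tissue-pixel concentration distribution; batch variability can
first be compensated by percentile rescaling to a reference cohort. The
positive-pixel ratio is then reported per 256 × 256 µm tile (heatmap), per
high-power field (group comparisons), and correlated tile-by-tile (Spearman)
against an externally supplied fibrosis-density map.

**Fluorescence assays** (`fluor_quant`). FMT fields: nuclei are counted by
edge detection (Gaussian-smoothed gradient magnitude with quantile hysteresis
thresholds, closing, hole filling, component labeling, minimum-area filter);
per-cell collagen-1 is the integrated field intensity divided by the nucleus
count, reported as fold change over the untreated control. Organoid
z-stacks: maximum-intensity projection, median denoising, rolling-ball
background subtraction, mean intensity per organoid ROI.

**Gene-set scores** (`geneset_score`). For a cell with UMI counts x_g,

    score = Σ_{g ∈ S*} x_g / Σ_g x_g

where S* are the set genes with ≥ 50 UMIs summed over all cells of the
compartment (hematopoietic and stromal filtered independently). Scores lie in
[0, 1] and are compared between cell groups with Wilcoxon rank-sum tests.

**Statistics** (`group_stats`). log2(x+1) normalization, per-feature min-max
scaling to [0, 1], two-sided Wilcoxon rank-sum (exact permutation null for
small tie-free samples, otherwise the tie- and continuity-corrected normal
approximation), and Benjamini–Hochberg adjustment.

**Synthetic data** (`synthetic_data`). Deterministic generators for all of
the above: Beer–Lambert forward-model slides with designed positive
fractions, disk-nucleus fluorescence fields with known counts and designed
intensities, z-stacks whose projection equals a known truth image,
multinomial UMI matrices with designed per-type set fractions, and two-group
log-normal protein tables with planted log2 fold changes.

## Worked example

Quantify a small synthetic cohort with a designed 30 % positive fraction:

```python
from marrowquant import synthetic_data as sd, stain_deconv as sdv, ihc_quant as iq

model = sdv.StainModel.hdab()
slides, masks = [], []
for i in range(3):
    spec = sd.IhcSimSpec(width_px=256, height_px=256, positive_fraction=0.3,
                         noise_sd=0.03, seed=i)
    slide, truth = sd.gen_ihc_slide(spec, model)
    slides.append(slide); masks.append(truth.tissue_mask)

cutoff = iq.pooled_positive_cutoff(slides, model, tissue_masks=masks)
print(f"pooled Otsu cutoff: {cutoff.cutoff:.4f} OD "
      f"({cutoff.n_pixels_pooled} tissue pixels)")
for slide, mask in zip(slides, masks):
    conc = sdv.deconvolve_slide(slide, model)
    hm = iq.positivity_heatmap(conc, mask, cutoff, tile_size_um=64,
                               microns_per_pixel=1.0, sample_id=slide.sample_id)
    print(f"{slide.sample_id}: positive ratio {hm.slide_ratio:.4f} "
          f"over {hm.ratio.size} tiles")
```

prints

```
pooled Otsu cutoff: 0.3111 OD (196608 tissue pixels)
sim-ihc-0: positive ratio 0.3000 over 16 tiles
sim-ihc-1: positive ratio 0.3000 over 16 tiles
sim-ihc-2: positive ratio 0.3000 over 16 tiles
```

The cutoff (0.31 OD) falls between the designed negative (0.1) and positive
(0.8) chromogen levels, and each slide's positive-pixel ratio recovers the
designed 30 % fraction. `hm.render("heatmap.png")` writes the blue-to-red
tile map; `hm.to_frame()` gives the per-tile counts.

The same pipelines are available from the shell via the `marrowquant`
command (`simulate`, `ihc-quant`, `fmt-quant`, `organoid-quant`,
`gene-score`, `prot-compare`); each run writes a `provenance.json` with the
effective configuration and input checksums. See `marrowquant --help`.

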