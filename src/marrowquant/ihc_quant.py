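"""Chromogen positivity calling and spatial summarization.

The chromogen (DAB) concentration map from stain deconvolution is reduced to
a binary positive/negative call with a single cutoff chosen by Otsu's method
on the *pooled* tissue-pixel distribution of the whole cohort — one cutoff
for all slides, so between-slide differences stay comparable.  Positive-pixel
ratios are then summarized per axis-aligned tile (default 256 x 256 microns)
into a heatmap, per high-power-field records for group comparisons, and a
tile-wise Spearman correlation against an externally supplied fibrosis
density map on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stain_deconv import (ConcentrationMaps, RgbSlide, StainModel,
                           deconvolve_slide, od_transform)

#: Total-OD threshold separating tissue from background white.
DEFAULT_TISSUE_OD_MIN = 0.15
#: Default Otsu histogram resolution (8-bit convention).
DEFAULT_N_BINS = 256
#: Default high-power-field edge length: a square with the area of a common
#: 40x objective field (0.237 mm^2).
DEFAULT_HPF_UM = float(np.sqrt(0.237e6))


class DegenerateInputError(ValueError):
    """Raised when a threshold is requested on constant input."""


class InsufficientDataError(ValueError):
    """Raised when fewer paired observations exist than a statistic needs."""


def tissue_mask(slide: RgbSlide, model: StainModel,
                od_min: float = DEFAULT_TISSUE_OD_MIN) -> np.ndarray:
    """Tissue = pixels whose total optical density exceeds ``od_min``.

    Background glass transmits nearly all light (total OD ~ 0) while any
    stained tissue absorbs; a small total-OD floor separates the two.
    """
    if od_min < 0:
        raise ValueError("od_min must be non-negative")
    od = od_transform(slide.pixels, model.background_intensity)
    return od.sum(axis=2) > od_min


def otsu_threshold(values=None, *, histogram=None,
                   n_bins: int = DEFAULT_N_BINS,
                   value_range: tuple[float, float] | None = None) -> float:
    """Histogram Otsu threshold: the bin edge maximizing between-class variance.

    Either raw ``values`` (histogrammed into ``n_bins`` over ``value_range``,
    default the data range) or a precomputed ``histogram=(counts, bin_edges)``
    may be given.  Candidate thresholds are the interior bin edges; between-
    class variance is computed from bin centers and counts; ties are broken by
    the lowest qualifying edge.  Constant input (a single occupied bin) has no
    split and raises :class:`DegenerateInputError`.
    """
    if (values is None) == (histogram is None):
        raise ValueError("give exactly one of values or histogram")
    if histogram is not None:
        counts, edges = histogram
        counts = np.asarray(counts, dtype=float)
        edges = np.asarray(edges, dtype=float)
        if counts.ndim != 1 or edges.shape != (counts.size + 1,):
            raise ValueError("histogram must be (counts, bin_edges)")
    else:
        vals = np.asarray(values, dtype=float).ravel()
        vals = vals[~np.isnan(vals)]
        if vals.size == 0 or np.unique(vals).size < 2:
            raise DegenerateInputError("need at least two distinct values")
        if value_range is None:
            value_range = (float(vals.min()), float(vals.max()))
        counts, edges = np.histogram(vals, bins=n_bins, range=value_range)
        counts = counts.astype(float)

    total = counts.sum()
    if total <= 0:
        raise DegenerateInputError("empty histogram")
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1]              # mass below edge k (k = 1..n-1)
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    tsum = (counts * centers).sum()
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise DegenerateInputError("all mass in a single bin; no split exists")
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / w0
        mu1 = (tsum - csum) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
    bcv[~valid] = -np.inf
    best = int(np.argmax(bcv))               # argmax returns the first (lowest) tie
    return float(edges[best + 1])


@dataclass
class PositivityCutoff:
    """Cohort-level chromogen cutoff with pooling provenance."""

    cutoff: float
    n_pixels_pooled: int
    histogram_bins: int
    cohort_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_pixels_pooled <= 0:
            raise ValueError("n_pixels_pooled must be positive")


def pooled_positive_cutoff(slides: list[RgbSlide], model: StainModel,
                           tissue_masks: list[np.ndarray] | None = None,
                           od_min: float = DEFAULT_TISSUE_OD_MIN,
                           n_bins: int = DEFAULT_N_BINS) -> PositivityCutoff:
    """Otsu cutoff on the pooled chromogen distribution of a cohort.

    Chromogen concentrations of every tissue pixel of every slide are pooled
    into one distribution and thresholded once; pooling is order-invariant.
    """
    if not slides:
        raise ValueError("need at least one slide")
    if tissue_masks is not None and len(tissue_masks) != len(slides):
        raise ValueError("one tissue mask per slide required")
    pooled = []
    for i, slide in enumerate(slides):
        mask = (tissue_masks[i] if tissue_masks is not None
                else tissue_mask(slide, model, od_min))
        conc = deconvolve_slide(slide, model)
        pooled.append(conc.chromogen[mask])
    values = np.concatenate(pooled)
    if values.size == 0:
        raise ValueError("no tissue pixels in the pooled cohort")
    cutoff = otsu_threshold(values, n_bins=n_bins)
    return PositivityCutoff(cutoff, int(values.size), n_bins,
                            [s.sample_id for s in slides])


def _tile_slices(n: int, tile_px: int) -> list[tuple[int, int]]:
    return [(start, min(start + tile_px, n)) for start in range(0, n, tile_px)]


@dataclass
class PositivityHeatmap:
    """Per-tile positive/tissue pixel counts and ratios on a regular grid.

    ``ratio`` is NaN for tiles without tissue; ``partial`` flags edge tiles
    clipped by the image border.  Tile counts partition the slide, so they sum
    exactly to the slide-level counts.
    """

    positive_px: np.ndarray     # int (rows, cols)
    tissue_px: np.ndarray       # int (rows, cols)
    ratio: np.ndarray           # float (rows, cols), NaN = missing
    partial: np.ndarray         # bool (rows, cols)
    tile_size_um: float
    microns_per_pixel: float
    sample_id: str = ""

    @property
    def slide_positive(self) -> int:
        return int(self.positive_px.sum())

    @property
    def slide_tissue(self) -> int:
        return int(self.tissue_px.sum())

    @property
    def slide_ratio(self) -> float:
        t = self.slide_tissue
        return self.slide_positive / t if t else float("nan")

    @property
    def tissue_weighted_mean_ratio(self) -> float:
        """Tissue-pixel-weighted mean of tile ratios; equals slide_ratio."""
        w = self.tissue_px.astype(float)
        ok = w > 0
        if not ok.any():
            return float("nan")
        return float((self.ratio[ok] * w[ok]).sum() / w[ok].sum())

    def to_frame(self) -> pd.DataFrame:
        rows, cols = self.ratio.shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        return pd.DataFrame({
            "tile_row": rr.ravel(), "tile_col": cc.ravel(),
            "tissue_px": self.tissue_px.ravel(),
            "positive_px": self.positive_px.ravel(),
            "ratio": self.ratio.ravel(),
            "partial": self.partial.ravel(),
        })

    def render(self, path) -> None:
        """Write a blue-to-red PNG of the tile ratios (grey = no tissue)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 6))
        cmap = plt.get_cmap("coolwarm").copy()
        cmap.set_bad("0.85")
        im = ax.imshow(np.ma.masked_invalid(self.ratio), cmap=cmap,
                       vmin=0.0, vmax=1.0, interpolation="nearest")
        fig.colorbar(im, ax=ax, label="positive-pixel ratio")
        ax.set_title(self.sample_id or "positivity heatmap")
        ax.set_xlabel(f"tile col ({self.tile_size_um:g} um)")
        ax.set_ylabel("tile row")
        fig.savefig(path, dpi=120)
        plt.close(fig)


def positivity_heatmap(conc: ConcentrationMaps, tissue: np.ndarray,
                       cutoff: PositivityCutoff | float,
                       tile_size_um: float = 256.0,
                       microns_per_pixel: float = 1.0,
                       sample_id: str = "") -> PositivityHeatmap:
    """Tile the slide and compute the positive-pixel ratio per tile.

    The grid is anchored at the top-left pixel; partial edge tiles are kept
    and flagged so the per-tile counts partition the slide exactly.
    """
    chromogen = conc.chromogen
    tissue = np.asarray(tissue, dtype=bool)
    if tissue.shape != chromogen.shape:
        raise ValueError("tissue mask shape does not match concentration maps")
    cut = cutoff.cutoff if isinstance(cutoff, PositivityCutoff) else float(cutoff)
    tile_px = int(round(tile_size_um / microns_per_pixel))
    if tile_px < 1:
        raise ValueError("tile size must be at least one pixel")

    positive = (chromogen > cut) & tissue
    h, w = chromogen.shape
    row_sl = _tile_slices(h, tile_px)
    col_sl = _tile_slices(w, tile_px)
    nr, nc = len(row_sl), len(col_sl)
    pos = np.zeros((nr, nc), dtype=np.int64)
    tis = np.zeros((nr, nc), dtype=np.int64)
    part = np.zeros((nr, nc), dtype=bool)
    for i, (r0, r1) in enumerate(row_sl):
        for j, (c0, c1) in enumerate(col_sl):
            pos[i, j] = positive[r0:r1, c0:c1].sum()
            tis[i, j] = tissue[r0:r1, c0:c1].sum()
            part[i, j] = (r1 - r0 < tile_px) or (c1 - c0 < tile_px)
    with np.errstate(invalid="ignore"):
        ratio = np.where(tis > 0, pos / np.maximum(tis, 1), np.nan)
    return PositivityHeatmap(pos, tis, ratio, part, tile_size_um,
                             microns_per_pixel, sample_id=sample_id)


@dataclass
class FieldPositivity:
    """One high-power-field record for group comparisons."""

    field_id: str
    positive_ratio: float
    mean_chromogen: float
    group: str = ""
    sample_id: str = ""


def per_field_positivity(conc: ConcentrationMaps, tissue: np.ndarray,
                         cutoff: PositivityCutoff | float,
                         field_size_um: float = DEFAULT_HPF_UM,
                         microns_per_pixel: float = 1.0,
                         group: str = "", sample_id: str = "",
                         ) -> list[FieldPositivity]:
    """Per-field positive ratio and mean chromogen concentration.

    Fields are tiles of ``field_size_um``; fields without tissue are excluded.
    """
    hm = positivity_heatmap(conc, tissue, cutoff, tile_size_um=field_size_um,
                            microns_per_pixel=microns_per_pixel,
                            sample_id=sample_id)
    chromogen = conc.chromogen
    tissue = np.asarray(tissue, dtype=bool)
    tile_px = int(round(field_size_um / microns_per_pixel))
    row_sl = _tile_slices(chromogen.shape[0], tile_px)
    col_sl = _tile_slices(chromogen.shape[1], tile_px)
    out = []
    for i, (r0, r1) in enumerate(row_sl):
        for j, (c0, c1) in enumerate(col_sl):
            if hm.tissue_px[i, j] == 0:
                continue
            sub_t = tissue[r0:r1, c0:c1]
            mean_c = float(chromogen[r0:r1, c0:c1][sub_t].mean())
            out.append(FieldPositivity(
                field_id=f"{sample_id or 'field'}_r{i}_c{j}",
                positive_ratio=float(hm.ratio[i, j]),
                mean_chromogen=mean_c, group=group, sample_id=sample_id))
    return out


def intensity_density_correlation(heatmap: PositivityHeatmap,
                                  density_map: np.ndarray,
                                  ) -> tuple[float, float, int]:
    """Spearman correlation between tile positivity and an external per-tile
    fibrosis density map on the same grid.

    Returns ``(rho, p, n_tiles)`` over tiles where both values are present.
    """
    density = np.asarray(density_map, dtype=float)
    if density.shape != heatmap.ratio.shape:
        raise ValueError("density map grid does not match the heatmap grid")
    ok = ~np.isnan(heatmap.ratio) & ~np.isnan(density)
    n = int(ok.sum())
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 paired tiles, got {n}")
    rho, p = stats.spearmanr(heatmap.ratio[ok], density[ok])
    return float(rho), float(p), n
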