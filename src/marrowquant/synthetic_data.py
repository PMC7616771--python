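"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its spec (including the seed): the IHC
generator runs the Beer-Lambert stain model *forward* so deconvolution can be
checked against designed concentrations; the fluorescence generators emit disk
"nuclei" with known counts and designed intensities; the counts generator
draws multinomial UMI vectors whose expected gene-set fraction equals the
designed ``p_set``; the proteomics generator plants a log2 fold change in a
known protein subset.  Truth masks/labels/tables accompany every output so no
downstream test needs manual annotation.

These fixtures emulate the *arithmetic* of the real assays, not their biology:
disks instead of nuclear morphology, flat stain levels instead of tissue
texture, no doublets/dropout in counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .stain_deconv import ConcentrationMaps, RgbSlide, StainModel
from .geneset_score import UmiCounts
from .group_stats import AbundanceTable

# Per-generator stream tags so one seed drives independent RNG streams.
_STREAM_IHC = 101
_STREAM_FLUOR = 202
_STREAM_ZSTACK = 303
_STREAM_COUNTS = 404
_STREAM_PROT = 505


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


class PlacementError(RuntimeError):
    """Raised when non-overlapping object placement is infeasible."""


# ---------------------------------------------------------------------------
# IHC brightfield slides
# ---------------------------------------------------------------------------

@dataclass
class IhcSimSpec:
    """Design of a synthetic two-stain brightfield slide.

    ``positive_fraction`` of tissue pixels get chromogen concentration
    ``chromogen_conc_pos`` (OD units), the rest ``chromogen_conc_neg``; all
    tissue pixels get ``counterstain_conc``.  Gaussian noise of sd ``noise_sd``
    is added in OD space (multiplicative in intensity, per Beer-Lambert).
    Non-tissue pixels are noise-free background white.
    """

    width_px: int = 512
    height_px: int = 512
    microns_per_pixel: float = 1.0
    positive_fraction: float = 0.3
    chromogen_conc_pos: float = 0.8
    chromogen_conc_neg: float = 0.1
    counterstain_conc: float = 0.4
    noise_sd: float = 0.0
    tissue_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be positive")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if not (self.chromogen_conc_pos > self.chromogen_conc_neg >= 0):
            raise ValueError("need chromogen_conc_pos > chromogen_conc_neg >= 0")
        if self.counterstain_conc < 0 or self.noise_sd < 0:
            raise ValueError("concentrations and noise_sd must be non-negative")
        if not 0.0 < self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must lie in (0, 1]")


@dataclass
class IhcGroundTruth:
    """Designed truth emitted with a synthetic slide."""

    positive_mask: np.ndarray   # bool H x W
    tissue_mask: np.ndarray     # bool H x W
    concentrations: ConcentrationMaps  # designed per-pixel stain concentrations


def beer_lambert_forward(conc: np.ndarray, model: StainModel,
                         ) -> np.ndarray:
    """Map H x W x 3 stain concentrations to float RGB intensities.

    ``OD = conc @ stain_vectors``, ``I = I0 * 10**(-OD)``; no quantization.
    """
    od = np.asarray(conc, dtype=float) @ model.stain_vectors
    return model.background_intensity * 10.0 ** (-od)


def gen_ihc_slide(spec: IhcSimSpec, model: StainModel | None = None,
                  ) -> tuple[RgbSlide, IhcGroundTruth]:
    """Synthesize a brightfield slide by the Beer-Lambert forward model.

    Returns the 8-bit slide plus ground truth (positive mask, tissue mask and
    the designed pre-noise concentration maps).
    """
    if model is None:
        model = StainModel.hdab()
    rng = _rng(spec.seed, _STREAM_IHC)
    h, w = spec.height_px, spec.width_px

    # Tissue = centered rectangle covering ~tissue_fraction of the image.
    s = np.sqrt(spec.tissue_fraction)
    th, tw = max(1, round(h * s)), max(1, round(w * s))
    r0, c0 = (h - th) // 2, (w - tw) // 2
    tissue = np.zeros((h, w), dtype=bool)
    tissue[r0:r0 + th, c0:c0 + tw] = True
    n_tissue = int(tissue.sum())

    # Positive pixels: an exact-count random subset of tissue pixels.
    n_pos = round(spec.positive_fraction * n_tissue)
    tissue_idx = np.flatnonzero(tissue.ravel())
    pos_idx = rng.choice(tissue_idx, size=n_pos, replace=False)
    positive = np.zeros(h * w, dtype=bool)
    positive[pos_idx] = True
    positive = positive.reshape(h, w)

    conc = np.zeros((h, w, 3))
    conc[..., 0] = np.where(positive, spec.chromogen_conc_pos,
                            np.where(tissue, spec.chromogen_conc_neg, 0.0))
    conc[..., 1] = np.where(tissue, spec.counterstain_conc, 0.0)

    od = conc @ model.stain_vectors
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=od.shape)
        od = od + np.where(tissue[..., None], noise, 0.0)
    intensity = model.background_intensity * 10.0 ** (-od)
    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)

    slide = RgbSlide(pixels, spec.microns_per_pixel,
                     sample_id=f"sim-ihc-{spec.seed}")
    truth = IhcGroundTruth(positive, tissue,
                           ConcentrationMaps(conc, clipping_policy="clip_at_zero"))
    return slide, truth


# ---------------------------------------------------------------------------
# Fluorescence fields and z-stacks
# ---------------------------------------------------------------------------

@dataclass
class FluorSimSpec:
    """Design of a paired nuclei/collagen fluorescence field.

    Nuclei are uniform disks of ``cell_radius_px`` at ``nucleus_intensity``
    over ``background``; the collagen channel is a uniform
    ``collagen_intensity`` field over the same background.  Gaussian noise of
    sd ``noise_sd`` is added independently to both channels.
    """

    n_cells: int = 40
    cell_radius_px: float = 8.0
    nucleus_intensity: float = 1000.0
    collagen_intensity: float = 300.0
    background: float = 100.0
    noise_sd: float = 20.0
    allow_touching: bool = False
    width_px: int = 512
    height_px: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if not self.cell_radius_px > 0:
            raise ValueError("cell_radius_px must be positive")
        if self.nucleus_intensity <= 0 or self.collagen_intensity <= 0:
            raise ValueError("intensities must be positive")
        if self.background < 0 or self.noise_sd < 0:
            raise ValueError("background and noise_sd must be non-negative")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("field dimensions must be positive")


@dataclass
class FluorGroundTruth:
    n_cells: int
    centers: np.ndarray              # (n, 2) row, col
    mean_collagen_per_cell: float    # designed field total / n_cells (nan if n=0)


def _place_disks(rng: np.random.Generator, n: int, radius: float,
                 h: int, w: int, allow_touching: bool,
                 min_gap_px: float = 6.0, border_clearance_px: float = 8.0,
                 max_tries_per_disk: int = 2000) -> np.ndarray:
    """Rejection-sample n disk centers; raises PlacementError when stuck.

    Disks stay ``border_clearance_px`` clear of the field border, emulating
    the standard practice of excluding border-clipped cells from counting
    (edge detectors cannot close a ring that leaves the field).
    """
    margin = radius + border_clearance_px
    if h - 2 * margin < 0 or w - 2 * margin < 0:
        raise PlacementError("field too small for the stated radius")
    centers: list[tuple[float, float]] = []
    min_d2 = (2 * radius + min_gap_px) ** 2
    tries = 0
    while len(centers) < n:
        if tries > max_tries_per_disk * max(n, 1):
            raise PlacementError(
                f"could not place {n} non-overlapping disks after {tries} tries")
        tries += 1
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if not allow_touching and any(
                (r - rr) ** 2 + (c - cc) ** 2 < min_d2 for rr, cc in centers):
            continue
        centers.append((r, c))
    return np.asarray(centers, dtype=float).reshape(n, 2)


def _paint_disks(shape: tuple[int, int], centers: np.ndarray, radius: float,
                 value: float, base: np.ndarray | None = None) -> np.ndarray:
    img = np.zeros(shape) if base is None else base
    h, w = shape
    rr = int(np.ceil(radius))
    for (cy, cx) in centers:
        y0, y1 = max(0, int(cy) - rr - 1), min(h, int(cy) + rr + 2)
        x0, x1 = max(0, int(cx) - rr - 1), min(w, int(cx) + rr + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
        img[y0:y1, x0:x1][inside] = value
    return img


def gen_fluor_pair(spec: FluorSimSpec,
                   ) -> tuple[np.ndarray, np.ndarray, FluorGroundTruth]:
    """Generate a (nuclei, collagen) uint16 image pair with ground truth.

    The designed per-cell collagen value is the noise-free field total divided
    by the number of cells (the per-count quantification convention).
    """
    rng = _rng(spec.seed, _STREAM_FLUOR)
    h, w = spec.height_px, spec.width_px
    centers = _place_disks(rng, spec.n_cells, spec.cell_radius_px, h, w,
                           spec.allow_touching)

    nuclei = np.full((h, w), float(spec.background))
    _paint_disks((h, w), centers, spec.cell_radius_px,
                 spec.background + spec.nucleus_intensity, base=nuclei)
    collagen = np.full((h, w), spec.background + spec.collagen_intensity)

    if spec.noise_sd > 0:
        nuclei = nuclei + rng.normal(0, spec.noise_sd, size=(h, w))
        collagen = collagen + rng.normal(0, spec.noise_sd, size=(h, w))

    nuclei_img = np.clip(np.rint(nuclei), 0, 65535).astype(np.uint16)
    collagen_img = np.clip(np.rint(collagen), 0, 65535).astype(np.uint16)

    total = float(h * w * (spec.background + spec.collagen_intensity))
    mean_per_cell = total / spec.n_cells if spec.n_cells > 0 else float("nan")
    return nuclei_img, collagen_img, FluorGroundTruth(
        spec.n_cells, centers, mean_per_cell)


@dataclass
class ZstackGroundTruth:
    truth_image: np.ndarray      # the designed max-projection, float
    roi_means: np.ndarray        # designed mean intensity per ROI
    roi_labels: np.ndarray       # int label map, 0 = background


def gen_zstack(n_slices: int, spec: FluorSimSpec, roi_count: int,
               roi_means: np.ndarray | None = None,
               ) -> tuple[np.ndarray, np.ndarray, ZstackGroundTruth]:
    """Generate an organoid-like z-stack with disjoint ROI masks.

    Each ROI is a uniform disk (radius ``spec.cell_radius_px``) at its designed
    mean intensity over a flat ``spec.background``; per-pixel noise is baked
    into the 2-D truth image, which is then distributed over slices so the
    per-pixel maximum of the stack equals the truth image exactly.

    Returns ``(stack [n_slices, H, W] float32, roi_labels, truth)``.
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    if roi_count < 1:
        raise ValueError("need at least one ROI")
    if roi_means is None:
        roi_means = 10.0 * 2.0 ** np.arange(roi_count)
    roi_means = np.asarray(roi_means, dtype=float)
    if roi_means.shape != (roi_count,):
        raise ValueError("roi_means length must equal roi_count")

    rng = _rng(spec.seed, _STREAM_ZSTACK)
    h, w = spec.height_px, spec.width_px
    radius = spec.cell_radius_px
    # Generous spacing keeps ROIs and their background-subtraction halos apart.
    centers = _place_disks(rng, roi_count, radius, h, w, allow_touching=False,
                           min_gap_px=6 * radius)

    truth = np.full((h, w), float(spec.background))
    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for i, ((cy, cx), m) in enumerate(zip(centers, roi_means), start=1):
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
        truth[inside] = spec.background + m
        labels[inside] = i
    if spec.noise_sd > 0:
        truth = np.maximum(truth + rng.normal(0, spec.noise_sd, size=(h, w)), 0.0)

    # Put each pixel's true value in one random slice; others get a damped copy.
    which = rng.integers(0, n_slices, size=(h, w))
    damp = rng.uniform(0.0, 0.8, size=(n_slices, h, w))
    stack = damp * truth[None, :, :]
    stack[which, yy, xx] = truth
    return stack.astype(np.float32), labels, ZstackGroundTruth(
        truth.astype(np.float32), roi_means, labels)


# ---------------------------------------------------------------------------
# UMI count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountsSimSpec:
    """Design of a multinomial UMI count matrix.

    ``cell_types`` lists (label, n_cells, p_set) triples: each cell of the
    type draws ``depth_per_cell`` UMIs with probability mass ``p_set`` spread
    evenly over the set genes and the rest evenly over the other genes, so the
    expected gene-set expression fraction per cell equals ``p_set``.
    """

    cell_types: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("ctrl", 500, 0.1), ("disease", 500, 0.3)])
    n_set_genes: int = 50
    n_other_genes: int = 500
    depth_per_cell: int = 10_000
    depth_distribution: str = "fixed"   # "fixed" | "lognormal"
    depth_lognormal_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_types:
            raise ValueError("cell_types must be non-empty")
        labels = [t[0] for t in self.cell_types]
        if len(set(labels)) != len(labels):
            raise ValueError("cell-type labels must be unique")
        for label, n, p in self.cell_types:
            if n < 0:
                raise ValueError(f"negative n_cells for type {label!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_set for type {label!r} outside [0, 1]")
        if self.n_set_genes < 1 or self.n_other_genes < 1:
            raise ValueError("gene counts must be positive")
        if self.depth_per_cell < 1:
            raise ValueError("depth_per_cell must be positive")
        if self.depth_distribution not in ("fixed", "lognormal"):
            raise ValueError("depth_distribution must be 'fixed' or 'lognormal'")


def set_gene_ids(spec: CountsSimSpec) -> list[str]:
    return [f"SETG{i:04d}" for i in range(spec.n_set_genes)]


def gen_counts(spec: CountsSimSpec, compartment: str = "stromal",
               ) -> tuple[UmiCounts, dict[str, float]]:
    """Draw the designed multinomial count matrix.

    Returns the counts container (cell-type labels as ``cell_groups``) and the
    designed per-type set fraction ``{label: p_set}``.
    """
    rng = _rng(spec.seed, _STREAM_COUNTS)
    genes = set_gene_ids(spec) + [f"OTHG{i:04d}" for i in range(spec.n_other_genes)]
    n_genes = len(genes)

    blocks, cell_ids, groups = [], [], []
    for label, n, p_set in spec.cell_types:
        probs = np.empty(n_genes)
        probs[:spec.n_set_genes] = p_set / spec.n_set_genes
        probs[spec.n_set_genes:] = (1.0 - p_set) / spec.n_other_genes
        if spec.depth_distribution == "fixed":
            depths = np.full(n, spec.depth_per_cell, dtype=np.int64)
        else:
            mu = np.log(spec.depth_per_cell) - spec.depth_lognormal_sigma ** 2 / 2
            depths = np.maximum(
                np.rint(rng.lognormal(mu, spec.depth_lognormal_sigma, size=n)),
                1).astype(np.int64)
        draws = np.vstack([rng.multinomial(d, probs) for d in depths]) \
            if n else np.zeros((0, n_genes), dtype=np.int64)
        blocks.append(draws)
        cell_ids.extend(f"{label}_{i:05d}" for i in range(n))
        groups.extend([label] * n)

    cells_by_genes = np.vstack(blocks)
    matrix = sp.csr_matrix(cells_by_genes.T)  # genes x cells
    counts = UmiCounts(matrix=matrix, gene_ids=genes, cell_ids=cell_ids,
                       cell_groups=np.asarray(groups), compartment=compartment)
    return counts, {label: p for label, _, p in spec.cell_types}


# ---------------------------------------------------------------------------
# Proteomics tables
# ---------------------------------------------------------------------------

def gen_proteomics(n_per_group: int, n_proteins: int, effect_log2fc: float,
                   seed: int = 0, frac_differential: float = 0.2,
                   within_sd_log2: float = 0.5,
                   ) -> tuple[AbundanceTable, list[str]]:
    """Two-group log-normal protein abundance table with a planted shift.

    The first ``frac_differential`` of proteins gain ``effect_log2fc`` on the
    log2 scale in group "B".  Returns the table and the shifted protein ids.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = _rng(seed, _STREAM_PROT)
    feature_ids = [f"PROT{i:04d}" for i in range(n_proteins)]
    sample_ids = ([f"A{i}" for i in range(n_per_group)]
                  + [f"B{i}" for i in range(n_per_group)])
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group,
                       index=sample_ids)

    base = rng.uniform(3.0, 8.0, size=n_proteins)
    log2ab = base[:, None] + rng.normal(
        0.0, within_sd_log2, size=(n_proteins, 2 * n_per_group))
    n_diff = round(frac_differential * n_proteins)
    log2ab[:n_diff, n_per_group:] += effect_log2fc
    data = pd.DataFrame(2.0 ** log2ab, index=feature_ids, columns=sample_ids)
    return AbundanceTable(data, groups), feature_ids[:n_diff]
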