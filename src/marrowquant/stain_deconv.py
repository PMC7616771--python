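"""Beer-Lambert optical-density color model and stain deconvolution.

Brightfield chromogenic stains absorb light, so transmitted intensity relates
to stain amount through the Beer-Lambert law: optical density
``OD = log10(I0 / I)`` is *linear* in stain concentration, and a pixel stained
by several dyes has an OD vector that is the concentration-weighted sum of the
dyes' unit OD color vectors.  Inverting that 3x3 linear system per pixel
("color deconvolution") separates, e.g., the brown DAB chromogen marking
galectin-1 from the blue hematoxylin counterstain, yielding one concentration
map per stain.  A percentile-based rescaling against a reference cohort
compensates for batch-to-batch staining variability before any thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Standard published H-DAB optical-density unit vectors
#: (hematoxylin, DAB); rows are unit-length RGB absorbance directions.
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
DAB_OD = np.array([0.269, 0.568, 0.778])

#: Intensity floor used in OD conversion so fully absorbed (0) pixels stay finite.
INTENSITY_FLOOR = 1.0


@dataclass
class RgbSlide:
    """A brightfield RGB image with its physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3), uint8
        8-bit RGB intensities.
    microns_per_pixel : float
        Physical size of one pixel edge in micrometers; must be positive.
    sample_id : str
        Identifier used in cohort provenance.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1 x 1")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class StainModel:
    """3x3 unit optical-density stain matrix plus background intensity.

    Row 1 is the chromogen of interest (DAB by default), row 2 the
    counterstain (hematoxylin-like), row 3 the orthogonal complement that
    closes the basis so the system is invertible.
    """

    stain_vectors: np.ndarray
    background_intensity: float = 255.0

    def __post_init__(self) -> None:
        self.stain_vectors = np.asarray(self.stain_vectors, dtype=float)
        if self.stain_vectors.shape != (3, 3):
            raise ValueError("stain_vectors must be 3 x 3")
        norms = np.linalg.norm(self.stain_vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("each stain vector must have unit Euclidean norm")
        if np.linalg.matrix_rank(self.stain_vectors) < 3:
            raise ValueError("stain matrix is rank-deficient (stains collinear)")
        if not 0 < self.background_intensity <= 255:
            raise ValueError("background_intensity must lie in (0, 255]")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.stain_vectors)

    @classmethod
    def hdab(cls, background_intensity: float = 255.0) -> "StainModel":
        """Default model: DAB chromogen + hematoxylin counterstain + complement."""
        return complete_stain_matrix(
            DAB_OD / np.linalg.norm(DAB_OD),
            HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD),
            background_intensity=background_intensity,
        )

    def to_dict(self) -> dict:
        return {
            "stain_vectors": self.stain_vectors.tolist(),
            "background_intensity": self.background_intensity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainModel":
        return cls(np.asarray(d["stain_vectors"], dtype=float),
                   float(d.get("background_intensity", 255.0)))


@dataclass
class ConcentrationMaps:
    """Per-stain concentration maps in OD units.

    ``maps`` has shape (H, W, 3): one plane per stain row of the model.
    ``clipping_policy`` records how negative solutions of the linear system
    were handled ("clip_at_zero" or "raw").
    """

    maps: np.ndarray
    clipping_policy: str = "clip_at_zero"
    stain_names: tuple[str, ...] = ("chromogen", "counterstain", "complement")

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3 or self.maps.shape[2] != 3:
            raise ValueError("maps must be H x W x 3")
        if self.clipping_policy == "clip_at_zero" and np.any(self.maps < 0):
            raise ValueError("clip_at_zero maps contain negative values")

    @property
    def chromogen(self) -> np.ndarray:
        return self.maps[..., 0]

    @property
    def counterstain(self) -> np.ndarray:
        return self.maps[..., 1]


def od_transform(pixels: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Convert RGB intensities to optical density per channel.

    ``OD_c = log10(I0 / max(I_c, 1))``; the intensity floor keeps OD finite for
    saturated (zero-intensity) pixels.  Monotone decreasing in intensity.
    """
    if not background_intensity > 0:
        raise ValueError("background intensity I0 must be positive")
    arr = np.asarray(pixels, dtype=float)
    return np.log10(background_intensity / np.maximum(arr, INTENSITY_FLOOR))


def deconvolve(od_image: np.ndarray, model: StainModel,
               clipping_policy: str = "clip_at_zero") -> ConcentrationMaps:
    """Solve per-pixel ``OD = concentrations @ stain_vectors`` for concentrations.

    Parameters
    ----------
    od_image : ndarray, shape (H, W, 3)
        Optical-density image (from :func:`od_transform`).
    model : StainModel
    clipping_policy : {"clip_at_zero", "raw"}
        Negative solutions are physically meaningless; the default clips them
        to zero, "raw" keeps them for diagnostics.
    """
    od = np.asarray(od_image, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("od_image must be H x W x 3")
    if clipping_policy not in ("clip_at_zero", "raw"):
        raise ValueError(f"unknown clipping_policy {clipping_policy!r}")
    conc = od @ model.inverse
    if clipping_policy == "clip_at_zero":
        conc = np.maximum(conc, 0.0)
    return ConcentrationMaps(conc, clipping_policy=clipping_policy)


def deconvolve_slide(slide: RgbSlide, model: StainModel,
                     clipping_policy: str = "clip_at_zero") -> ConcentrationMaps:
    """OD-transform a slide with the model's I0 and deconvolve it."""
    od = od_transform(slide.pixels, model.background_intensity)
    return deconvolve(od, model, clipping_policy=clipping_policy)


def complete_stain_matrix(v1: np.ndarray, v2: np.ndarray,
                          background_intensity: float = 255.0) -> StainModel:
    """Build a full StainModel from two measured stain vectors.

    The third row is the normalized cross product of the first two, so two
    measured dyes always yield an invertible 3x3 system.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    for v in (v1, v2):
        if v.shape != (3,) or not np.isclose(np.linalg.norm(v), 1.0, atol=1e-9):
            raise ValueError("stain vectors must be unit 3-vectors")
    v3 = np.cross(v1, v2)
    n3 = np.linalg.norm(v3)
    if n3 < 1e-9:
        raise ValueError("stain vectors are collinear; cannot complete basis")
    return StainModel(np.vstack([v1, v2, v3 / n3]),
                      background_intensity=background_intensity)


@dataclass
class StainReferenceStats:
    """Per-stain robust maxima (a high percentile over tissue pixels) of a
    reference cohort, used as the normalization target."""

    robust_max: np.ndarray  # length-3, one per stain
    percentile: float = 99.0

    def __post_init__(self) -> None:
        self.robust_max = np.asarray(self.robust_max, dtype=float)
        if self.robust_max.shape != (3,):
            raise ValueError("robust_max must have one entry per stain")


def reference_stats(conc: ConcentrationMaps, tissue_mask: np.ndarray,
                    percentile: float = 99.0) -> StainReferenceStats:
    """Compute per-stain robust maxima over tissue pixels of one slide."""
    mask = np.asarray(tissue_mask, dtype=bool)
    if mask.shape != conc.maps.shape[:2]:
        raise ValueError("tissue mask shape does not match concentration maps")
    if not mask.any():
        raise ValueError("tissue mask is empty")
    vals = conc.maps[mask]  # (n_tissue, 3)
    return StainReferenceStats(np.percentile(vals, percentile, axis=0),
                               percentile=percentile)


def normalize_stains(conc: ConcentrationMaps, reference: StainReferenceStats,
                     tissue_mask: np.ndarray) -> tuple[ConcentrationMaps, np.ndarray]:
    """Rescale each stain map so its robust maximum matches the reference.

    Each stain plane is multiplied by ``reference robust max / source robust
    max`` computed over tissue pixels only; a stain whose source robust max is
    zero is left unscaled with a warning.  Returns the normalized maps and the
    per-stain scale factors actually applied (provenance).
    """
    src = reference_stats(conc, tissue_mask, percentile=reference.percentile)
    scale = np.ones(3)
    for i in range(3):
        if src.robust_max[i] == 0:
            logger.warning(
                "stain %d has zero robust max on this slide; normalization skipped",
                i)
        else:
            scale[i] = reference.robust_max[i] / src.robust_max[i]
    out = ConcentrationMaps(conc.maps * scale[np.newaxis, np.newaxis, :],
                            clipping_policy=conc.clipping_policy,
                            stain_names=conc.stain_names)
    return out, scale
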