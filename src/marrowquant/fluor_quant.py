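"""Fluorescence quantifiers for the FMT and organoid fibrosis assays.

FMT (fibroblast-to-myofibroblast transition) fields come as paired grayscale
images: a nuclear channel and a collagen-1 channel.  Cells are counted on the
nuclear channel by edge detection (Gaussian-smoothed gradient magnitude with
hysteresis, morphological closing, hole filling, connected components, a
minimum-area filter), and the per-cell collagen readout is the integrated
collagen intensity of the field divided by the nucleus count; condition means
are reported as fold change over the untreated control, which cancels camera
gain.

Organoid z-stacks are reduced by maximum-intensity projection, median-filter
denoised, background-subtracted with a rolling ball, and summarized as the
mean intensity inside each organoid ROI.

Touching nuclei are not split (no watershed): the counter is exact only for
well-separated nuclei, which is the regime the plating density targets.
Quantile-based hysteresis thresholds adapt to exposure but assume the field
contains real edges; a field with *no* nuclei and nonzero noise can produce
spurious detections, so empty wells should be excluded upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.morphology import closing, disk
from skimage.restoration import rolling_ball

logger = logging.getLogger(__name__)


@dataclass
class NucleiDetectionParams:
    """Edge-detection nuclei counter settings.

    Hysteresis thresholds are *quantiles* of the gradient-magnitude
    distribution, so they track exposure; they sit high (0.95/0.99) because
    nuclei edges occupy a small fraction of the field and lower quantiles fall
    at the noise floor.  ``closing_radius_px`` bridges small gaps in edge
    rings; ``min_area_px`` rejects specks below a plausible nucleus area.
    """

    smoothing_sigma: float = 2.0
    low_quantile: float = 0.95
    high_quantile: float = 0.99
    closing_radius_px: int = 2
    min_area_px: int = 30

    def __post_init__(self) -> None:
        if not 0 <= self.low_quantile <= self.high_quantile <= 1:
            raise ValueError("need 0 <= low_quantile <= high_quantile <= 1")
        if self.smoothing_sigma < 0 or self.closing_radius_px < 0:
            raise ValueError("sigma and closing radius must be non-negative")
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be non-negative")


@dataclass
class NucleiSegmentation:
    """Labeled nuclei with areas, centroids and the parameters used."""

    labels: np.ndarray               # int H x W, 0 = background
    n_cells: int
    areas_px: np.ndarray
    centroids: np.ndarray            # (n, 2) row, col
    params: NucleiDetectionParams


def detect_nuclei(image: np.ndarray,
                  params: NucleiDetectionParams | None = None,
                  ) -> NucleiSegmentation:
    """Count nuclei by edge detection on a 2-D grayscale image.

    Pipeline: Gaussian smoothing -> gradient magnitude with hysteresis (canny)
    -> morphological closing -> hole filling -> connected components ->
    minimum-area filter.  Deterministic for fixed parameters.
    """
    params = params or NucleiDetectionParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclei image must be 2-D grayscale")
    if np.ptp(img) == 0:  # constant image has no edges; canny border artifacts
        return NucleiSegmentation(np.zeros(img.shape, dtype=np.int32), 0,
                                  np.empty(0), np.empty((0, 2)), params)
    edges = canny(img, sigma=params.smoothing_sigma,
                  low_threshold=params.low_quantile,
                  high_threshold=params.high_quantile, use_quantiles=True)
    mask = edges
    if params.closing_radius_px > 0:
        mask = closing(mask, disk(params.closing_radius_px))
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask)
    if n:
        areas = ndi.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= params.min_area_px) + 1
        relabel = np.zeros(n + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, keep.size + 1)
        labels = relabel[labels]
        n = keep.size
        areas = areas[keep - 1]
        centroids = np.asarray(ndi.center_of_mass(
            labels > 0, labels, index=np.arange(1, n + 1))).reshape(n, 2)
    else:
        areas = np.empty(0)
        centroids = np.empty((0, 2))
    return NucleiSegmentation(labels, int(n), np.asarray(areas, dtype=float),
                              centroids, params)


class ZeroCellError(ValueError):
    """Raised when a per-cell quantity is requested for a field with no cells."""


@dataclass
class FieldQuant:
    """Per-field FMT quantification record."""

    field_id: str
    n_cells: int
    collagen_sum: float
    per_cell_intensity: float
    mode: str = "per_count"
    condition: str = ""
    well_id: str = ""


def per_cell_collagen(collagen_image: np.ndarray, seg: NucleiSegmentation,
                      mode: str = "per_count", dilation_px: int = 2,
                      field_id: str = "", condition: str = "",
                      well_id: str = "") -> FieldQuant:
    """Collagen-1 intensity per cell for one field.

    ``per_count`` (default): integrated field intensity / nucleus count — the
    counting-only convention of the assay.  ``per_mask``: mean collagen inside
    the nuclei masks dilated by ``dilation_px``.  A field with zero detected
    cells has no per-cell value and raises :class:`ZeroCellError`.
    """
    col = np.asarray(collagen_image, dtype=float)
    if col.shape != seg.labels.shape:
        raise ValueError("collagen image shape does not match segmentation")
    if seg.n_cells == 0:
        raise ZeroCellError("no cells detected; per-cell intensity undefined")
    total = float(col.sum())
    if mode == "per_count":
        per_cell = total / seg.n_cells
    elif mode == "per_mask":
        mask = seg.labels > 0
        if dilation_px > 0:
            mask = ndi.binary_dilation(mask, structure=disk(dilation_px))
        per_cell = float(col[mask].mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FieldQuant(field_id=field_id, n_cells=seg.n_cells,
                      collagen_sum=total, per_cell_intensity=per_cell,
                      mode=mode, condition=condition, well_id=well_id)


def normalize_to_control(fields: list[FieldQuant], control_condition: str,
                         ) -> pd.DataFrame:
    """Condition-level fold changes of mean per-cell intensity over control.

    Returns one row per condition with n fields, mean per-cell intensity and
    its fold change against the control condition (control maps to 1.0).
    """
    if not fields:
        raise ValueError("no fields given")
    df = pd.DataFrame([{"condition": f.condition,
                        "per_cell_intensity": f.per_cell_intensity}
                       for f in fields])
    if control_condition not in set(df["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent")
    means = df.groupby("condition", sort=False)["per_cell_intensity"].agg(
        ["mean", "count"])
    ctrl = means.loc[control_condition, "mean"]
    out = means.rename(columns={"mean": "mean_per_cell_intensity",
                                "count": "n_fields"}).reset_index()
    out["fold_change"] = out["mean_per_cell_intensity"] / ctrl
    return out


def max_intensity_projection(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the slice axis of an (n_slices, H, W) stack."""
    stack = np.asarray(zstack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("zstack must be (n_slices, H, W) with >= 1 slice")
    return stack.max(axis=0)


def rolling_ball_subtract(image: np.ndarray, radius_px: float = 50.0,
                          ) -> np.ndarray:
    """Subtract a rolling-ball background estimate, floored at zero.

    The background is the grayscale opening of the image by a ball of the
    given radius (the classic rolling-ball estimator): smooth background
    wider than the ball is removed, structures narrower than the ball are
    preserved.  Output satisfies ``0 <= out <= image``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if radius_px < 1:
        raise ValueError("radius must be at least 1 px")
    if 2 * radius_px > max(img.shape):
        raise ValueError("ball radius exceeds the image extent")
    background = rolling_ball(img, radius=radius_px)
    return np.maximum(img - background, 0.0)


@dataclass
class OrganoidQuant:
    """Per-organoid intensity after projection, denoising and background
    subtraction."""

    organoid_id: int
    roi_area_px: int
    mean_intensity: float
    channel: str = ""

    def __post_init__(self) -> None:
        if self.mean_intensity < 0:
            raise ValueError("mean_intensity must be non-negative")


def organoid_roi_intensity(projected: np.ndarray, roi_labels: np.ndarray,
                           median_size: int = 3, radius_px: float = 50.0,
                           channel: str = "") -> list[OrganoidQuant]:
    """Mean background-subtracted intensity inside each labeled ROI.

    ``projected`` is a max-intensity projection; processing is median-filter
    denoising then rolling-ball subtraction.  Empty ROI labels are skipped
    with a warning; output order follows ascending label.
    """
    img = np.asarray(projected, dtype=float)
    labels = np.asarray(roi_labels)
    if labels.shape != img.shape:
        raise ValueError("ROI label map shape does not match image")
    if median_size > 1:
        img = ndi.median_filter(img, size=median_size)
    img = rolling_ball_subtract(img, radius_px=radius_px)
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        area = int(mask.sum())
        if area == 0:
            logger.warning("ROI %d is empty; skipped", lab)
            continue
        out.append(OrganoidQuant(int(lab), area, float(img[mask].mean()),
                                 channel=channel))
    return out
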