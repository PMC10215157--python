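"""White-lesion segmentation of H&E micrographs.

The chain mirrors a classical whole-image preprocessing recipe for
vacuole quantification: exclusion masking of irrelevant white structures
(sinuses, central veins) -> per-channel quantile contrast stretch ->
per-channel Otsu binarization at a configurable fraction of the Otsu level
-> logical fusion of the three binary planes (AND: white must be bright in
every channel) -> removal of components smaller than 10 px, which always
appear as noise and are too small for shape descriptors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from skimage.measure import label

from .synth import ImageRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    otsu_scale: float = 0.5          # threshold = otsu_scale * Otsu level
    fusion_mode: str = "AND"         # "AND" or "OR" across RGB planes
    min_region_area: int = 10        # px^2; components below are dropped
    contrast_saturation: float = 0.01  # clipped quantile per tail
    connectivity: int = 8            # 4 or 8, for component labelling

    def __post_init__(self) -> None:
        if not 0 < self.otsu_scale <= 2:
            raise ValueError("otsu_scale must be in (0, 2]")
        if self.fusion_mode not in ("AND", "OR"):
            raise ValueError("fusion_mode must be 'AND' or 'OR'")
        if self.min_region_area < 1:
            raise ValueError("min_region_area must be >= 1")
        if not 0 <= self.contrast_saturation < 0.5:
            raise ValueError("contrast_saturation must be in [0, 0.5)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2


@dataclass
class LesionMask:
    """Binary segmentation result plus the parameters that produced it."""

    mask: np.ndarray                      # bool, H x W
    thresholds: tuple[float, float, float]  # raw per-channel Otsu levels
    params: SegmentationParams
    stage_pixel_counts: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return int(label(self.mask, connectivity=self.params.skimage_connectivity).max())


class OtsuResult(NamedTuple):
    level: float
    degenerate: bool


def enhance_contrast(image: np.ndarray, saturation: float = 0.01) -> np.ndarray:
    """Per-channel linear stretch of the [p, 1-p] quantiles onto [0, 255].

    Values outside the quantile span are clipped; a constant channel is
    returned unchanged.  Rounding is to nearest.
    """
    image = np.asarray(image)
    out = np.empty_like(image, dtype=np.uint8)
    for ch in range(image.shape[-1]):
        plane = image[..., ch].astype(np.float64)
        lo, hi = np.quantile(plane, [saturation, 1.0 - saturation])
        if hi <= lo:
            out[..., ch] = image[..., ch]
            continue
        stretched = (plane - lo) * 255.0 / (hi - lo)
        out[..., ch] = np.clip(np.rint(stretched), 0, 255).astype(np.uint8)
    return out


def otsu_threshold(channel: np.ndarray) -> OtsuResult:
    """256-bin Otsu level maximizing between-class variance.

    The cut between bins k and k+1 is represented by the level k + 0.5;
    ties among argmax cuts are resolved by averaging the tied levels.  A
    constant channel is degenerate and returns its own value.
    """
    values = np.asarray(channel).ravel()
    if values.size == 0:
        raise ValueError("empty pixel set")
    hist = np.bincount(values.astype(np.intp), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) == 1:
        return OtsuResult(float(np.nonzero(hist)[0][0]), True)
    bins = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]                      # class 0 = bins 0..k
    w1 = n - w0
    s0 = np.cumsum(hist * bins)[:-1]
    mu_total = (hist * bins).sum()
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(255)
    mu0 = np.where(valid, s0 / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (mu_total - s0) / np.where(w1 > 0, w1, 1), 0.0)
    sigma_b[valid] = (w0 * w1)[valid] * (mu0 - mu1)[valid] ** 2
    best = sigma_b.max()
    ties = np.nonzero(np.isclose(sigma_b, best, rtol=0, atol=best * 1e-12))[0]
    level = float(np.mean(ties + 0.5))
    return OtsuResult(level, False)


def binarize_fuse(
    image: np.ndarray,
    exclusion_mask: np.ndarray | None,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Per-channel thresholding at ``otsu_scale * Otsu level`` and fusion.

    Excluded pixels do not enter the Otsu histograms and are forced to
    background in the fused result.  Returns (binary, per-channel levels).
    """
    image = np.asarray(image)
    keep = None if exclusion_mask is None else ~np.asarray(exclusion_mask, dtype=bool)
    planes = []
    levels = []
    degenerate = []
    for ch in range(3):
        plane = image[..., ch]
        sample = plane if keep is None else plane[keep]
        res = otsu_threshold(sample)
        levels.append(res.level)
        degenerate.append(res.degenerate)
        if res.degenerate:
            # a constant plane holds no white/non-white contrast
            planes.append(np.zeros(plane.shape, dtype=bool))
        else:
            planes.append(plane.astype(np.float64) >= params.otsu_scale * res.level)
    if all(degenerate):
        warnings.warn("all three channels are constant; returning an empty mask")
        fused = np.zeros(image.shape[:2], dtype=bool)
    elif params.fusion_mode == "AND":
        fused = planes[0] & planes[1] & planes[2]
    else:
        fused = planes[0] | planes[1] | planes[2]
    if keep is not None:
        fused &= keep
    return fused, (levels[0], levels[1], levels[2])


def remove_small_regions(
    binary: np.ndarray, min_region_area: int = 10, connectivity: int = 8
) -> np.ndarray:
    """Drop components with area < ``min_region_area`` (boundary case kept)."""
    binary = np.asarray(binary, dtype=bool)
    labelled = label(binary, connectivity=1 if connectivity == 4 else 2)
    counts = np.bincount(labelled.ravel())
    keep = counts >= min_region_area
    keep[0] = False
    return keep[labelled]


def segment(
    record: ImageRecord, params: SegmentationParams = SegmentationParams()
) -> LesionMask:
    """Full chain: contrast stretch -> Otsu binarize+fuse -> small-region removal."""
    enhanced = enhance_contrast(record.image, params.contrast_saturation)
    fused, levels = binarize_fuse(enhanced, record.exclusion_mask, params)
    clean = remove_small_regions(fused, params.min_region_area, params.connectivity)
    counts = {
        "image_pixels": int(record.image.shape[0] * record.image.shape[1]),
        "excluded": 0
        if record.exclusion_mask is None
        else int(np.count_nonzero(record.exclusion_mask)),
        "fused_foreground": int(np.count_nonzero(fused)),
        "final_foreground": int(np.count_nonzero(clean)),
    }
    logger.debug("segment %s: %s", record.image_id or "<image>", counts)
    return LesionMask(mask=clean, thresholds=levels, params=params, stage_pixel_counts=counts)
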