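"""Edema index, relative-ADC statistics and tumor diameter.

EI = (tumor voxels + edema voxels) / tumor voxels on the resampled grid, a
volumetric measure of peritumoral edema relative to tumor size (EI = 1 means
no edema).  rADC statistics normalize tumor ADC values by the mean ADC of a
user-supplied reference region (intended: contralateral normal-appearing
white matter).  The diameter is the 3-D Feret diameter of the tumor
voxel-center point cloud in physical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .grids import InputError, SegmentationMasks, VoxelGrid

__all__ = [
    "ImagingMetrics",
    "edema_index",
    "radc_stats",
    "tumor_diameter",
    "compute_metrics",
]


@dataclass
class ImagingMetrics:
    ei: float
    radc_mean: float
    radc_max: float
    radc_min: float
    radc_dif: float
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.ei < 1:
            raise ValueError("EI cannot be below 1")
        if not (self.radc_min <= self.radc_mean <= self.radc_max):
            raise ValueError("rADC ordering violated")


def edema_index(masks: SegmentationMasks) -> float:
    """(|tumor| + |edema|) / |tumor| from voxel counts."""
    n_tumor = int(masks.tumor.sum())
    if n_tumor == 0:
        raise InputError("empty tumor mask")
    return (n_tumor + int(masks.edema.sum())) / n_tumor


def radc_stats(
    adc: VoxelGrid,
    masks: SegmentationMasks,
    trim: float = 0.005,
) -> tuple[float, float, float, float]:
    """(rADCmean, rADCmax, rADCmin, rADCdif) for one patient.

    Each statistic of the tumor ADC values is divided by the mean ADC over
    the reference region.  The voxelwise extrema exclude the top and bottom
    ``trim`` fraction of tumor voxels (floor(trim * n) from each tail,
    default 0.5%) as a guard against single-voxel acquisition noise; set
    ``trim=0`` for raw extrema.
    """
    if adc.shape != masks.shape:
        raise InputError("ADC grid and masks are not aligned")
    tumor_vals = adc.values[masks.tumor]
    ref_vals = adc.values[masks.reference]
    if tumor_vals.size == 0 or ref_vals.size == 0:
        raise InputError("tumor and reference masks must be nonempty")
    ref_mean = float(ref_vals.mean())
    if ref_mean <= 0:
        raise InputError(f"reference mean ADC must be positive, got {ref_mean}")

    srt = np.sort(tumor_vals)
    drop = int(np.floor(trim * srt.size))
    kept = srt[drop: srt.size - drop] if drop > 0 else srt
    r_mean = float(tumor_vals.mean()) / ref_mean
    r_max = float(kept.max()) / ref_mean
    r_min = float(kept.min()) / ref_mean
    return r_mean, r_max, r_min, r_max - r_min


def tumor_diameter(masks: SegmentationMasks, spacing=None) -> float:
    """Maximal pairwise distance (mm) between tumor voxel centers.

    Computed on the convex hull of the voxel-center point set; falls back to
    brute force for degenerate (collinear/coplanar/tiny) clouds.  A single
    voxel has diameter 0 by the voxel-center convention.
    """
    if spacing is None:
        spacing = masks.spacing
    idx = np.argwhere(masks.tumor)
    if idx.shape[0] == 0:
        raise InputError("empty tumor mask")
    pts = idx * np.asarray(spacing, dtype=float)
    if pts.shape[0] == 1:
        return 0.0
    if pts.shape[0] > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate geometry; use all points
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).max())


def compute_metrics(
    adc: VoxelGrid,
    masks: SegmentationMasks,
    trim: float = 0.005,
) -> ImagingMetrics:
    """All imaging metrics for one patient."""
    ei = edema_index(masks)
    r_mean, r_max, r_min, r_dif = radc_stats(adc, masks, trim=trim)
    diam = tumor_diameter(masks)
    return ImagingMetrics(ei, r_mean, r_max, r_min, r_dif, diam)
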