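"""Grid resampling and gradient-anchored intensity normalization.

Volumes are assumed already bias-corrected and co-registered; this module
brings them to the working voxel size (default 1 x 1 x 3 mm) and maps the
contrast-enhanced intensities to a common 0-255 range before clustering.

The normalization window is anchored to the image *gradient*: voxels whose
3-D gradient magnitude exceeds its within-mask mean are treated as edge
voxels, and the mean/SD of the original intensities over those edge voxels
define a linear window [mu - 3 sigma, mu + 3 sigma] that is mapped to
[0, 255] and clipped.  Because the gradient magnitude of a*I + b is a times
that of I, the edge set is unchanged under positive affine rescaling and the
window rescales with the data, so the mapping is affine-invariant.
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk

from .grids import InputError, VoxelGrid

__all__ = [
    "DegenerateInputError",
    "resample",
    "gradient_normalize",
    "GradientNormalizer",
]


class DegenerateInputError(ValueError):
    """Image is constant (zero-width intensity window) within the mask."""


def _to_sitk(grid: VoxelGrid) -> sitk.Image:
    # sitk indexes arrays as [z, y, x]; our grids are [i, j, k]
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    return img


def _from_sitk(img: sitk.Image) -> VoxelGrid:
    return VoxelGrid(
        sitk.GetArrayFromImage(img).T.astype(float),
        tuple(img.GetSpacing()),
        tuple(img.GetOrigin()),
    )


def resample(
    grid: VoxelGrid,
    target_spacing: tuple[float, float, float],
    mode: str = "linear",
) -> VoxelGrid:
    """Resample a grid to ``target_spacing`` preserving its physical extent.

    Intensity grids should use ``mode="linear"``; binary masks must use
    ``mode="nearest"`` so labels stay binary.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise InputError(f"target spacing must be positive, got {target_spacing}")
    if mode not in ("linear", "nearest"):
        raise InputError(f"unknown resampling mode {mode!r}")

    img = _to_sitk(grid)
    new_size = [
        max(1, int(round(n * s / ts)))
        for n, s, ts in zip(grid.shape, grid.spacing, target_spacing)
    ]
    interp = sitk.sitkLinear if mode == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        target_spacing,
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
        True,  # nearest-neighbour extrapolation at the half-voxel boundary
    )
    return _from_sitk(out)


def resample_mask(mask: np.ndarray, spacing, target_spacing) -> np.ndarray:
    """Nearest-neighbour mask resampling; returns a boolean array."""
    g = VoxelGrid(np.asarray(mask, dtype=float), spacing)
    # nearest-neighbour interpolation of a {0,1} field; values stay in {0,1},
    # so > 0.5 is exact and ties cannot occur (break toward background anyway)
    return resample(g, target_spacing, mode="nearest").values > 0.5


def _gradient_magnitude(values: np.ndarray, spacing) -> np.ndarray:
    gi, gj, gk = np.gradient(values, *spacing)
    return np.sqrt(gi * gi + gj * gj + gk * gk)


def gradient_normalize(
    grid: VoxelGrid,
    body_mask: np.ndarray | None = None,
    n_sigma: float = 3.0,
) -> VoxelGrid:
    """Map intensities to [0, 255] with a gradient-anchored window.

    Parameters
    ----------
    grid : VoxelGrid
        Intensity volume.
    body_mask : bool array, optional
        Region over which the window is estimated (e.g. the head); the whole
        grid when omitted.  The mapping is applied everywhere.
    n_sigma : float
        Half-width of the window in edge-intensity SDs (default 3).
    """
    if body_mask is None:
        body_mask = np.ones(grid.shape, dtype=bool)
    body_mask = np.asarray(body_mask).astype(bool)
    if body_mask.shape != grid.shape:
        raise InputError("body mask shape does not match grid")
    if not body_mask.any():
        raise InputError("body mask is empty")

    inside = grid.values[body_mask]
    if np.ptp(inside) == 0:
        raise DegenerateInputError("image is constant within the body mask")

    gmag = _gradient_magnitude(grid.values, grid.spacing)
    gm = gmag[body_mask]
    edge = body_mask & (gmag > gm.mean())
    if not edge.any():  # flat image except isolated jumps; fall back to mask
        edge = body_mask
    ev = grid.values[edge]
    mu, sigma = float(ev.mean()), float(ev.std())
    if sigma == 0:
        # edge voxels share one intensity (e.g. thin synthetic boundary);
        # window over the full within-mask range keeps the map monotone
        lo, hi = float(inside.min()), float(inside.max())
    else:
        lo, hi = mu - n_sigma * sigma, mu + n_sigma * sigma
    scaled = np.clip((grid.values - lo) / (hi - lo) * 255.0, 0.0, 255.0)
    return VoxelGrid(scaled, grid.spacing, grid.origin)


class GradientNormalizer:
    """Transformer wrapper around :func:`gradient_normalize`.

    ``fit`` estimates the intensity window on one volume (optionally within a
    body mask); ``transform`` applies the frozen window, so a window learned
    on one volume can be reused on an aligned one.
    """

    def __init__(self, n_sigma: float = 3.0):
        self.n_sigma = n_sigma

    def get_params(self, deep: bool = True) -> dict:
        return {"n_sigma": self.n_sigma}

    def set_params(self, **params) -> "GradientNormalizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, grid: VoxelGrid, body_mask: np.ndarray | None = None) -> "GradientNormalizer":
        if body_mask is None:
            body_mask = np.ones(grid.shape, dtype=bool)
        body_mask = np.asarray(body_mask).astype(bool)
        inside = grid.values[body_mask]
        if inside.size == 0:
            raise InputError("body mask is empty")
        if np.ptp(inside) == 0:
            raise DegenerateInputError("image is constant within the body mask")
        gmag = _gradient_magnitude(grid.values, grid.spacing)
        edge = body_mask & (gmag > gmag[body_mask].mean())
        if not edge.any():
            edge = body_mask
        ev = grid.values[edge]
        mu, sigma = float(ev.mean()), float(ev.std())
        if sigma == 0:
            self.window_ = (float(inside.min()), float(inside.max()))
        else:
            self.window_ = (mu - self.n_sigma * sigma, mu + self.n_sigma * sigma)
        return self

    def transform(self, grid: VoxelGrid) -> VoxelGrid:
        if not hasattr(self, "window_"):
            raise RuntimeError("GradientNormalizer is not fitted")
        lo, hi = self.window_
        scaled = np.clip((grid.values - lo) / (hi - lo) * 255.0, 0.0, 255.0)
        return VoxelGrid(scaled, grid.spacing, grid.origin)

    def fit_transform(self, grid: VoxelGrid, body_mask: np.ndarray | None = None) -> VoxelGrid:
        return self.fit(grid, body_mask).transform(grid)
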