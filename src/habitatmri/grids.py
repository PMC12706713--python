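"""Voxel grids and segmentation masks.

A :class:`VoxelGrid` is a 3-D scalar field (one MRI sequence) with physical
voxel spacing and origin, stored in index order ``values[i, j, k]`` with
spacing ``(si, sj, sk)`` in millimetres.  :class:`SegmentationMasks` bundles
the tumor, peritumoral-edema and normal-reference masks aligned to the
patient's intensity grids.  NIfTI round-trips go through nibabel with a
diagonal affine (voxel-center convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "SegmentationMasks",
    "InputError",
    "load_nifti",
]


class InputError(ValueError):
    """Invalid or inconsistent pipeline input."""


@dataclass
class VoxelGrid:
    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InputError(f"expected a 3-D volume, got shape {self.values.shape}")
        if self.values.size == 0:
            raise InputError("empty grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def aligned_with(self, other: "VoxelGrid | SegmentationMasks") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


def load_nifti(path: str | Path) -> VoxelGrid:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return VoxelGrid(np.asanyarray(img.dataobj, dtype=float), spacing, origin)


@dataclass
class SegmentationMasks:
    """Tumor / edema / reference masks on a common grid.

    Tumor and edema must be disjoint (edema is the peritumoral shell, not
    part of the enhancing tumor) and the tumor must be nonempty.
    """

    tumor: np.ndarray
    edema: np.ndarray
    reference: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor).astype(bool)
        self.edema = np.asarray(self.edema).astype(bool)
        self.reference = np.asarray(self.reference).astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if not (self.tumor.shape == self.edema.shape == self.reference.shape):
            raise InputError("masks must share one shape")
        if any(s <= 0 for s in self.spacing):
            raise InputError("spacing must be strictly positive")
        if not self.tumor.any():
            raise InputError("tumor mask is empty")
        if np.any(self.tumor & self.edema):
            raise InputError("tumor and edema masks overlap")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tumor.shape  # type: ignore[return-value]

    def _grid(self, arr: np.ndarray) -> VoxelGrid:
        return VoxelGrid(arr.astype(float), self.spacing, self.origin)

    def save(self, directory: str | Path, prefix: str = "mask") -> dict[str, Path]:
        directory = Path(directory)
        paths = {}
        for name in ("tumor", "edema", "reference"):
            p = directory / f"{prefix}_{name}.nii.gz"
            img = nib.Nifti1Image(getattr(self, name).astype(np.uint8), self._affine())
            nib.save(img, str(p))
            paths[name] = p
        return paths

    def _affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def load(cls, tumor: str | Path, edema: str | Path, reference: str | Path) -> "SegmentationMasks":
        t, e, r = (load_nifti(p) for p in (tumor, edema, reference))
        for g in (e, r):
            if not t.aligned_with(g):
                raise InputError("masks are not aligned on a common grid")
        return cls(t.values > 0.5, e.values > 0.5, r.values > 0.5, t.spacing, t.origin)
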