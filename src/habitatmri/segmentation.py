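"""Voxel-wise K-means habitat segmentation.

Each tumor is partitioned on its own voxels (per-patient clustering) in the
two-channel feature space (normalized T1-CE, ADC).  With k = 3 the clusters
are relabeled into the three canonical habitats by their centroid signature:

* Habitat 3 ("nonviable tissue"): the centroid with maximal ADC;
* Habitat 1 ("high-enhancement cellular"): of the remaining two, the higher
  T1-CE centroid;
* Habitat 2 ("low-enhancement cellular"): the lower T1-CE centroid.

The fourth conceivable signature (high enhancement together with high ADC)
is not given its own label: if the maximal-ADC centroid also has the
strictly maximal T1-CE the same rule is applied and a warning is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .grids import InputError, VoxelGrid

__all__ = [
    "DegeneracyError",
    "HabitatMap",
    "HabitatFractions",
    "HabitatSegmenter",
    "cluster_voxels",
    "assign_habitats",
    "habitat_fractions",
]


class DegeneracyError(ValueError):
    """Fewer distinct feature vectors than clusters requested."""


@dataclass
class HabitatFractions:
    f1: float
    f2: float
    f3: float

    def __post_init__(self) -> None:
        total = self.f1 + self.f2 + self.f3
        if not np.isclose(total, 1.0):
            raise ValueError(f"fractions must sum to 1, got {total}")

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3])

    def as_percent(self, decimals: int = 1) -> tuple[float, float, float]:
        """Fractions as percentages rounded for reporting (one decimal)."""
        return tuple(round(100.0 * f, decimals) for f in self.as_array())


@dataclass
class HabitatMap:
    """Per-voxel habitat labels inside the tumor mask.

    ``labels`` holds 0 outside the tumor and 1..k inside; ``centroids`` are
    the per-cluster mean (T1-CE, ADC) feature pairs in display units, row h-1
    for habitat h.
    """

    labels: np.ndarray
    centroids: np.ndarray
    k: int
    tumor: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.tumor = np.asarray(self.tumor).astype(bool)
        if self.labels.shape != self.tumor.shape:
            raise InputError("labels and tumor mask shapes differ")
        if np.any(self.labels[~self.tumor] != 0):
            raise InputError("labels found outside the tumor mask")
        inside = self.labels[self.tumor]
        if inside.size and (inside.min() < 1 or inside.max() > self.k):
            raise InputError("labels inside tumor must lie in 1..k")

    def counts(self) -> np.ndarray:
        inside = self.labels[self.tumor]
        return np.bincount(inside, minlength=self.k + 1)[1:]


def _relabel_rule(centroids: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Permutation old-cluster-index -> habitat label for k = 3 centroids."""
    notes: list[str] = []
    adc = centroids[:, 1]
    t1 = centroids[:, 0]
    h3 = int(np.argmax(adc))
    if t1[h3] > max(np.delete(t1, h3)):
        notes.append(
            "maximal-ADC cluster also has maximal T1-CE "
            "(high-enhancement/low-cellularity signature); labeled Habitat 3 by rule"
        )
    rest = [i for i in range(3) if i != h3]
    h1 = rest[0] if t1[rest[0]] >= t1[rest[1]] else rest[1]
    h2 = rest[1] if h1 == rest[0] else rest[0]
    perm = np.empty(3, dtype=int)
    perm[h1], perm[h2], perm[h3] = 1, 2, 3
    return perm, notes


def assign_habitats(hmap: HabitatMap) -> HabitatMap:
    """Relabel k = 3 clusters into canonical habitats (pure permutation)."""
    if hmap.k != 3:
        raise InputError("habitat assignment is defined for k = 3")
    perm, notes = _relabel_rule(hmap.centroids)
    labels = np.zeros_like(hmap.labels)
    centroids = np.empty_like(hmap.centroids)
    for old in range(3):
        labels[hmap.labels == old + 1] = perm[old]
        centroids[perm[old] - 1] = hmap.centroids[old]
    return HabitatMap(labels, centroids, 3, hmap.tumor, hmap.warnings + notes)


def habitat_fractions(hmap: HabitatMap) -> HabitatFractions:
    counts = hmap.counts()
    total = counts.sum()
    if total == 0:
        raise InputError("empty tumor")
    f = counts / total
    f = np.pad(f, (0, max(0, 3 - len(f))))[:3]
    return HabitatFractions(*map(float, f))


class HabitatSegmenter:
    """K-means habitat clusterer over paired (T1-CE, ADC) tumor voxels.

    Parameters
    ----------
    k : int
        Number of clusters (3 in the canonical analysis; habitat relabeling
        is only applied when k = 3).
    random_state : int
        Seed for k-means++ initialization.
    n_restarts : int
        Independent k-means restarts; the lowest-SSE run is kept.
    standardize : bool
        Z-score each channel within the tumor before clustering.  The two
        channels live on very different scales (0-255 vs ~10^3 ADC units);
        without standardization ADC would dominate the distance.
    """

    def __init__(
        self,
        k: int = 3,
        random_state: int = 0,
        n_restarts: int = 10,
        standardize: bool = True,
    ):
        self.k = k
        self.random_state = random_state
        self.n_restarts = n_restarts
        self.standardize = standardize

    def get_params(self, deep: bool = True) -> dict:
        return {
            "k": self.k,
            "random_state": self.random_state,
            "n_restarts": self.n_restarts,
            "standardize": self.standardize,
        }

    def set_params(self, **params) -> "HabitatSegmenter":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(
        self,
        t1ce: VoxelGrid,
        adc: VoxelGrid,
        tumor: np.ndarray,
    ) -> "HabitatSegmenter":
        tumor = np.asarray(tumor).astype(bool)
        if t1ce.shape != adc.shape or t1ce.shape != tumor.shape:
            raise InputError("T1-CE, ADC and tumor mask are not aligned")
        if not np.allclose(t1ce.spacing, adc.spacing):
            raise InputError("T1-CE and ADC spacing differ")
        n_vox = int(tumor.sum())
        if n_vox < self.k:
            raise InputError(f"tumor has {n_vox} voxels, fewer than k={self.k}")

        X_raw = np.column_stack([t1ce.values[tumor], adc.values[tumor]])
        if np.unique(X_raw, axis=0).shape[0] < self.k:
            raise DegeneracyError(
                f"fewer than k={self.k} distinct (T1-CE, ADC) feature vectors"
            )
        if self.standardize:
            mu = X_raw.mean(axis=0)
            sd = X_raw.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X_raw - mu) / sd
        else:
            X = X_raw

        km = KMeans(
            n_clusters=self.k,
            init="k-means++",
            n_init=self.n_restarts,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn chatter on tiny inputs
            raw_labels = km.fit_predict(X)

        labels = np.zeros(tumor.shape, dtype=int)
        labels[tumor] = raw_labels + 1
        centroids = np.vstack(
            [X_raw[raw_labels == c].mean(axis=0) for c in range(self.k)]
        )
        hmap = HabitatMap(labels, centroids, self.k, tumor)
        if self.k == 3:
            hmap = assign_habitats(hmap)
        self.habitat_map_ = hmap
        self.labels_ = hmap.labels
        self.centroids_ = hmap.centroids
        self.inertia_ = float(km.inertia_)
        self.fractions_ = habitat_fractions(hmap)
        return self

    def fit_predict(self, t1ce: VoxelGrid, adc: VoxelGrid, tumor: np.ndarray) -> np.ndarray:
        return self.fit(t1ce, adc, tumor).labels_


def cluster_voxels(
    t1ce: VoxelGrid,
    adc: VoxelGrid,
    tumor: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    standardize: bool = True,
) -> HabitatMap:
    """Cluster tumor voxels and (for k = 3) relabel into canonical habitats."""
    seg = HabitatSegmenter(k=k, random_state=seed, n_restarts=n_restarts, standardize=standardize)
    return seg.fit(t1ce, adc, tumor).habitat_map_
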