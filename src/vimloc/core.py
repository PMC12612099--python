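"""Shared domain types and geometric conventions.

All voxel-wise quantities in this package live on the thalamic mask only:
fields are stored as flat arrays of length ``V`` (the number of mask voxels),
in the order given by :attr:`VoxelGrid.mask_indices`.  Voxel indices are
0-based; millimetre coordinates come from the NIfTI affine.  Labelling is
binary (``K = 2``): class 1 is "Vim", class 0 is "not Vim".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

K_CLASSES = 2

__all__ = [
    "K_CLASSES",
    "VoxelGrid",
    "ConnectivityFeatureSet",
    "LabelField",
    "ProbabilityField",
    "AtlasPrior",
    "CRFParams",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A voxel lattice with mm geometry, restricted to a thalamic mask.

    Parameters
    ----------
    shape
        Voxel counts per axis (three positive integers).
    voxel_size_mm
        Voxel edge lengths in millimetres.
    affine
        4x4 voxel-index -> mm homogeneous map (NIfTI convention).
    mask_indices
        ``(V, 3)`` integer array of the mask voxel indices, in the flat
        storage order used by every field defined on this grid.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    mask_indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )
        affine = np.asarray(self.affine, dtype=float)
        idx = np.asarray(self.mask_indices, dtype=np.intp)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "mask_indices", idx)

        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if idx.ndim != 2 or idx.shape[1] != 3 or idx.shape[0] < 1:
            raise ValueError("mask_indices must be a nonempty (V, 3) array")
        if (idx < 0).any() or (idx >= np.asarray(self.shape)).any():
            raise ValueError("mask_indices outside grid shape")
        if len(np.unique(idx, axis=0)) != idx.shape[0]:
            raise ValueError("mask_indices contains duplicates")
        if not np.all(np.isfinite(self.voxel_to_mm(idx))):
            raise ValueError("affine maps mask voxels to non-finite coordinates")

    @property
    def n_voxels(self) -> int:
        """Number of mask voxels ``V``."""
        return int(self.mask_indices.shape[0])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def voxel_to_mm(self, index: np.ndarray) -> np.ndarray:
        """Map voxel indices to mm coordinates through the affine.

        Accepts a single index triple or an ``(n, 3)`` array; raises on
        indices outside the grid.
        """
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        if (idx < 0).any() or (idx >= np.asarray(self.shape)).any():
            raise IndexError(f"voxel index outside grid shape {self.shape}")
        hom = np.c_[idx, np.ones(len(idx))]
        mm = hom @ self.affine.T
        out = mm[:, :3]
        return out[0] if np.asarray(index).ndim == 1 else out

    def mm_to_voxel(self, coord_mm: np.ndarray, round_to_int: bool = False) -> np.ndarray:
        """Inverse of :meth:`voxel_to_mm`; optionally round to the nearest voxel."""
        xyz = np.atleast_2d(np.asarray(coord_mm, dtype=float))
        hom = np.c_[xyz, np.ones(len(xyz))]
        idx = (hom @ np.linalg.inv(self.affine).T)[:, :3]
        if round_to_int:
            idx = np.rint(idx).astype(np.intp)
        return idx[0] if np.asarray(coord_mm).ndim == 1 else idx

    def mask_mm_coordinates(self) -> np.ndarray:
        """mm coordinates of all mask voxels, ``(V, 3)``, in storage order."""
        return self.voxel_to_mm(self.mask_indices)

    def dense_from_flat(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a flat mask field into a dense 3D volume."""
        values = np.asarray(values)
        if values.shape[0] != self.n_voxels:
            raise ValueError("flat field length does not match mask size")
        out = np.full(self.shape, fill, dtype=values.dtype if values.dtype.kind == "f" else float)
        i, j, k = self.mask_indices.T
        out[i, j, k] = values
        return out

    def flat_from_dense(self, volume: np.ndarray) -> np.ndarray:
        """Extract the mask voxels of a dense 3D volume as a flat field."""
        volume = np.asarray(volume)
        if volume.shape != self.shape:
            raise ValueError(f"volume shape {volume.shape} != grid shape {self.shape}")
        i, j, k = self.mask_indices.T
        return volume[i, j, k]

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=atol)
            and self.n_voxels == other.n_voxels
            and np.array_equal(self.mask_indices, other.mask_indices)
        )


def _require_same_grid(a: VoxelGrid, b: VoxelGrid, what: str) -> None:
    if not a.same_geometry(b):
        raise ValueError(f"{what}: voxel grids differ (shape/affine/mask mismatch)")


@dataclass
class ConnectivityFeatureSet:
    """A ``V x d`` matrix of named, max-normalised tract-density features.

    Each column is one tract-density map (streamline counts from the thalamic
    seed to a named target ROI, normalised to a maximum of 1), restricted to
    the thalamic mask and flattened in grid storage order.
    """

    grid: VoxelGrid
    feature_names: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.feature_names = list(self.feature_names)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (voxels x features)")
        if self.X.shape[0] != self.grid.n_voxels:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but grid has {self.grid.n_voxels} mask voxels"
            )
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length != number of columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if not np.isfinite(self.X).all():
            raise ValueError("features contain non-finite values")
        if self.X.min() < -1e-12 or self.X.max() > 1 + 1e-12:
            raise ValueError("normalised tract densities must lie in [0, 1]")
        np.clip(self.X, 0.0, 1.0, out=self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(
                f"feature {name!r} not present; available: {self.feature_names}"
            ) from None
        return self.X[:, j]


@dataclass
class LabelField:
    """Binary Vim labels on the mask, with their one-hot encoding."""

    grid: VoxelGrid
    y: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.shape != (self.grid.n_voxels,):
            raise ValueError("y must be a flat vector of length V")
        uniq = np.unique(y)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        self.y = y.astype(np.int8)

    @property
    def one_hot(self) -> np.ndarray:
        """``(V, 2)`` one-hot matrix T: row i has a 1 in column y_i."""
        T = np.zeros((self.grid.n_voxels, K_CLASSES))
        T[np.arange(self.grid.n_voxels), self.y] = 1.0
        return T

    @property
    def n_labelled(self) -> int:
        return int(self.y.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_labelled == 0

    def volume_mm3(self) -> float:
        return self.n_labelled * self.grid.voxel_volume_mm3


@dataclass
class ProbabilityField:
    """Per-voxel posterior marginals ``Q`` over the two classes."""

    grid: VoxelGrid
    Q: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if Q.shape != (self.grid.n_voxels, K_CLASSES):
            raise ValueError(f"Q must be (V, {K_CLASSES})")
        if not np.isfinite(Q).all():
            raise ValueError("marginals contain non-finite values")
        if (Q < -1e-12).any() or (Q > 1 + 1e-12).any():
            raise ValueError("marginals outside [0, 1]")
        if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("marginal rows must sum to 1")
        self.Q = Q

    @property
    def vim_probability(self) -> np.ndarray:
        """Posterior probability of class 1 ("Vim") per voxel."""
        return self.Q[:, 1]

    def binarize(self, threshold: float = 0.5) -> LabelField:
        return LabelField(self.grid, (self.vim_probability >= threshold).astype(np.int8))


@dataclass
class AtlasPrior:
    """Group-average Vim probability per voxel, in native-grid storage order."""

    grid: VoxelGrid
    g: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        if g.shape != (self.grid.n_voxels,):
            raise ValueError("g must be a flat vector of length V")
        if not np.isfinite(g).all() or g.min() < -1e-12 or g.max() > 1 + 1e-12:
            raise ValueError("prior probabilities must lie in [0, 1]")
        self.g = np.clip(g, 0.0, 1.0)


@dataclass
class CRFParams:
    """Learned CRF parameters.

    ``W`` is the ``d' x 2`` unary coefficient matrix on the expanded feature
    vector (``d' = 4 d + 1``: raw features, three polynomial power blocks, and
    the atlas-prior term).  ``rho`` scales the kernel-weighted Potts pairwise
    cost and ``gamma`` is the Gaussian kernel length scale.
    """

    W: np.ndarray
    rho: float
    gamma: float
    powers: tuple[float, float, float] = (2.0, 0.5, 0.2)
    lambda1: float = 0.0
    lambda2: float = 0.0
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[1] != K_CLASSES:
            raise ValueError(f"W must be (d', {K_CLASSES})")
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be nonnegative")
        self.powers = tuple(float(p) for p in self.powers)
        if len(self.powers) != 3:
            raise ValueError("exactly three polynomial powers expected")

    @property
    def expanded_dim(self) -> int:
        return self.W.shape[0]

    def raw_dim(self) -> int:
        """Raw feature count d implied by d' = 4 d + 1."""
        d, rem = divmod(self.expanded_dim - 1, 4)
        if rem != 0:
            raise ValueError(f"expanded dimension {self.expanded_dim} is not 4d + 1")
        return d
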