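"""Voxel grids and scalar brain maps.

The analysis lives on a :class:`BrainGrid`: a regular isotropic voxel lattice
with an affine mapping voxel indices to MNI millimetre coordinates and a
boolean analysis mask.  Scalar fields on the grid (effect size, variance, Z,
p, Q) are carried by :class:`VolumeMap`, which stores only the in-mask voxel
values, in the C-order of the mask, together with a role tag used for
validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import nibabel as nib
import numpy as np

__all__ = ["BrainGrid", "VolumeMap", "ROLES"]

#: Recognised map roles and their validity constraints.
ROLES = ("effect_size", "variance", "z", "p", "q")


@dataclass(frozen=True)
class BrainGrid:
    """Common voxel grid: shape, voxel→mm affine, and analysis mask."""

    shape: Tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError("mask shape does not match grid shape")
        if not mask.any():
            raise ValueError("analysis mask is empty")
        scales = np.linalg.norm(affine[:3, :3], axis=0)
        if not np.allclose(scales, scales[0], rtol=1e-6):
            raise ValueError("grid must have isotropic voxels")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    # -- geometry ---------------------------------------------------------

    @property
    def voxel_size_mm(self) -> float:
        return float(np.linalg.norm(self.affine[:3, 0]))

    @property
    def n_voxels(self) -> int:
        """Number of voxels inside the analysis mask."""
        return int(self.mask.sum())

    def ijk_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out

    def mm_to_ijk(self, mm: np.ndarray) -> np.ndarray:
        mm = np.atleast_2d(np.asarray(mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return mm @ inv[:3, :3].T + inv[:3, 3]

    def mask_indices(self) -> np.ndarray:
        """Linear (C-order) indices of in-mask voxels."""
        return np.flatnonzero(self.mask.ravel(order="C"))

    def mask_coords_mm(self) -> np.ndarray:
        """(V, 3) MNI mm coordinates of the in-mask voxels, mask order."""
        ijk = np.array(np.nonzero(self.mask)).T
        return self.ijk_to_mm(ijk)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BrainGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self.affine, other.affine)
            and np.array_equal(self.mask, other.mask)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.affine.tobytes(), self.mask.tobytes()))

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_box(
        cls,
        half_extent_mm: float = 30.0,
        voxel_mm: float = 2.0,
        mask_radius_mm: float | None = 28.0,
        center_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "BrainGrid":
        """Compact cubic grid around ``center_mm`` with a spherical mask.

        Suitable for simulations and tests; a full-brain grid is built with
        :meth:`mni152`.
        """
        n = int(round(2 * half_extent_mm / voxel_mm)) + 1
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        affine[:3, 3] = np.asarray(center_mm) - half_extent_mm
        shape = (n, n, n)
        if mask_radius_mm is None:
            mask = np.ones(shape, dtype=bool)
        else:
            ijk = np.indices(shape).reshape(3, -1).T
            mm = ijk * voxel_mm + affine[:3, 3]
            r2 = ((mm - np.asarray(center_mm)) ** 2).sum(axis=1)
            mask = (r2 <= mask_radius_mm**2).reshape(shape)
        return cls(shape, affine, mask)

    @classmethod
    def mni152(cls, voxel_mm: float = 2.0) -> "BrainGrid":
        """Full MNI152 bounding-box grid with a coarse ellipsoidal GM mask.

        The mask is an axis-aligned ellipsoid centred at (0, -18, 8) mm with
        semi-axes (65, 85, 70) mm — a deliberately coarse stand-in for a
        gray-matter mask, replaceable by any user-supplied NIfTI mask via
        :meth:`from_mask_nifti`.
        """
        # MNI152 2 mm bounding box: x -90..90, y -126..90, z -72..108
        nx = int(round(180 / voxel_mm)) + 1
        ny = int(round(216 / voxel_mm)) + 1
        nz = int(round(180 / voxel_mm)) + 1
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        affine[:3, 3] = (-90.0, -126.0, -72.0)
        shape = (nx, ny, nz)
        ijk = np.indices(shape).reshape(3, -1).T
        mm = ijk * voxel_mm + affine[:3, 3]
        center = np.array([0.0, -18.0, 8.0])
        semi = np.array([65.0, 85.0, 70.0])
        r2 = (((mm - center) / semi) ** 2).sum(axis=1)
        mask = (r2 <= 1.0).reshape(shape)
        return cls(shape, affine, mask)

    @classmethod
    def from_mask_nifti(cls, path) -> "BrainGrid":
        img = nib.load(str(path))
        mask = np.asarray(img.get_fdata()) > 0.5
        return cls(tuple(mask.shape), np.asarray(img.affine), mask)

    def mask_to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)


@dataclass
class VolumeMap:
    """A scalar field over the in-mask voxels of a :class:`BrainGrid`."""

    grid: BrainGrid
    values: np.ndarray
    role: str = "effect_size"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_voxels,):
            raise ValueError(
                f"values must have one entry per in-mask voxel "
                f"({self.grid.n_voxels}), got shape {self.values.shape}"
            )
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values inside the mask")
        if self.role == "variance" and not np.all(self.values > 0):
            raise ValueError("variance map must be strictly positive")
        if self.role == "p" and not (
            np.all(self.values > 0) and np.all(self.values <= 1)
        ):
            raise ValueError("p map values must lie in (0, 1]")

    def to_3d(self, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.grid.shape, fill, dtype=float)
        out[self.grid.mask] = self.values
        return out

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.to_3d(np.nan).astype(np.float32), self.grid.affine)

    @classmethod
    def from_3d(cls, grid: BrainGrid, arr: np.ndarray, role: str = "effect_size") -> "VolumeMap":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != grid.shape:
            raise ValueError("array shape does not match grid")
        return cls(grid, arr[grid.mask], role)

    def value_at_mm(self, mm) -> float:
        """Value at the in-mask voxel nearest to an mm coordinate."""
        ijk = np.rint(self.grid.mm_to_ijk(mm)[0]).astype(int)
        arr = self.to_3d(np.nan)
        v = arr[tuple(ijk)]
        if np.isnan(v):
            raise ValueError(f"coordinate {mm} is outside the analysis mask")
        return float(v)
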