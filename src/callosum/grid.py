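"""Voxel grid bookkeeping shared by all volume-producing modules.

Everything in the package lives in one common space: a regular grid with a
diagonal voxel->world affine (RAS-style axes: +x right, +y anterior,
+z superior) and a voxel-centered convention — the world coordinate of voxel
index ``i`` along an axis is ``affine @ (i, j, k, 1)`` and nearest-voxel
mapping rounds to the closest center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Grid", "world_to_voxel", "nearest_voxel"]


@dataclass(frozen=True)
class Grid:
    """A 3-D sampling grid: shape, physical voxel size and affine."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if self.affine is None:
            # center the grid so the midsagittal plane x=0 falls between columns
            trans = [-(n - 1) / 2.0 * v for n, v in zip(self.shape, self.voxel_size)]
            aff = np.diag([*self.voxel_size, 1.0])
            aff[:3, 3] = trans
            object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def min_voxel_size(self) -> float:
        return min(self.voxel_size)

    def voxel_centers_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel indices, shape (n, 3)."""
        idx = np.atleast_2d(idx)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_space(self, other: "Grid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def new_volume(self, dtype=np.float64, channels: int | None = None) -> np.ndarray:
        shape = self.shape if channels is None else (*self.shape, channels)
        return np.zeros(shape, dtype=dtype)

    def to_nifti(self, data: np.ndarray) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(data), self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "Grid":
        zooms = img.header.get_zooms()[:3]
        return cls(tuple(img.shape[:3]), tuple(float(z) for z in zooms), np.asarray(img.affine))


def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world-mm points (n, 3) to continuous voxel coordinates."""
    inv = np.linalg.inv(affine)
    return np.atleast_2d(points) @ inv[:3, :3].T + inv[:3, 3]


def nearest_voxel(points: np.ndarray, affine: np.ndarray, shape) -> np.ndarray:
    """Nearest voxel indices for world points; points are clipped to the grid."""
    cont = world_to_voxel(points, affine)
    idx = np.rint(cont).astype(np.int64)
    return np.clip(idx, 0, np.asarray(shape) - 1)
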